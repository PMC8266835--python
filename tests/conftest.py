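import numpy as np
import pytest

from nigra import phantom


@pytest.fixture(scope="session")
def small_config() -> phantom.PhantomConfig:
    """Compact study-condition config shared by unit tests: default ROI
    geometry on a trimmed grid, 4 subjects per group."""
    return phantom.PhantomConfig(grid_shape=(44, 52, 36), n_per_group=4, seed=11)


@pytest.fixture(scope="session")
def quiet_config(small_config) -> phantom.PhantomConfig:
    """Same conditions with noise switched off (exactness checks)."""
    import dataclasses

    return dataclasses.replace(small_config, noise=phantom.NoiseSpec().silent())


@pytest.fixture(scope="session")
def atlas(small_config) -> phantom.PhantomAtlas:
    return phantom.generate_atlas(small_config)


@pytest.fixture(scope="session")
def pd_record() -> phantom.SubjectRecord:
    """A maximally severe left-lateralized PD record."""
    return phantom.SubjectRecord(
        subject_id="pd900",
        group="PD",
        age=65.0,
        sex="M",
        most_affected_side="left",
        updrs3=40.0,
        hy=2.5,
        duration_years=8.0,
        ledd=600.0,
        d_nm=1.0,
        d_r2=1.0,
        d_ki=1.0,
    )


@pytest.fixture(scope="session")
def hc_record() -> phantom.SubjectRecord:
    return phantom.SubjectRecord(subject_id="hc900", group="HC", age=66.0, sex="F")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
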