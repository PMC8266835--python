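"""Voxelwise GLM, contrasts, and permutation FWE / small-volume correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nigra import voxel_stats
from nigra.voxel_stats import (
    Contrast,
    build_design,
    contrast_t,
    fit_glm,
    permutation_fwe,
    small_volume_correct,
    t_to_z,
)


def _subjects(n_per_group=8, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["PD"] * n_per_group + ["HC"] * n_per_group,
            "age": rng.normal(65, 8, n),
            "sex": rng.choice(["M", "F"], n),
        }
    )


def _null_maps(n, shape=(5, 5, 4), seed=1):
    rng = np.random.default_rng(seed)
    return [rng.standard_normal(shape) for _ in range(n)]


class TestBuildDesign:
    def test_group_effect_columns(self):
        d = build_design(_subjects(), scheme="group_effect")
        assert d.columns == ["PD", "HC", "age", "sex"]
        assert np.allclose(d.frame["PD"] + d.frame["HC"], 1.0)

    def test_covariate_columns_split_the_centered_covariate(self):
        subs = _subjects()
        cov = np.arange(len(subs), dtype=float)
        d = build_design(subs, covariate=cov, scheme="group_by_covariate")
        centered = cov - cov.mean()
        assert np.allclose(d.frame["covariate_PD"] + d.frame["covariate_HC"], centered)
        # each split column vanishes on the other group's rows
        assert np.allclose(d.frame["covariate_PD"] * d.frame["HC"], 0.0)
        assert np.allclose(d.frame["covariate_HC"] * d.frame["PD"], 0.0)

    def test_constant_covariate_raises_rank_error(self):
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(_subjects(), covariate=np.ones(16), scheme="group_by_covariate")


class TestFitGlm:
    def test_identical_maps_give_zero_residuals(self):
        subs = _subjects(4)
        const = np.full((3, 3, 3), 2.0)
        fit = fit_glm([const] * 8, build_design(subs), np.ones((3, 3, 3), bool))
        assert np.allclose(fit.sigma2, 0.0, atol=1e-20)
        # both group intercepts reproduce the constant
        assert np.allclose(fit.beta[0], 2.0) and np.allclose(fit.beta[1], 2.0)

    def test_single_voxel_matches_normal_equations_oracle(self):
        subs = _subjects(6, seed=5)
        rng = np.random.default_rng(9)
        vals = rng.normal(size=12)
        maps = [np.full((1, 1, 1), v) for v in vals]
        design = build_design(subs)
        fit = fit_glm(maps, design, np.ones((1, 1, 1), bool))
        X = design.matrix
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ vals)
        assert np.allclose(fit.beta.ravel(), beta_oracle)

    def test_intercept_only_gives_voxel_mean(self):
        rng = np.random.default_rng(2)
        maps = [rng.standard_normal((2, 2, 2)) for _ in range(6)]
        frame = pd.DataFrame({"intercept": np.ones(6)})
        design = voxel_stats.DesignMatrix(frame=frame, scheme="group_effect")
        fit = fit_glm(maps, design, np.ones((2, 2, 2), bool))
        assert np.allclose(fit.beta[0], np.mean(maps, axis=0).ravel())

    def test_too_few_subjects_errors(self):
        subs = _subjects(2)  # 4 subjects vs 4 design columns
        with pytest.raises(ValueError, match="fewer subjects"):
            fit_glm(_null_maps(4), build_design(subs), np.ones((5, 5, 4), bool))


class TestContrastT:
    def test_two_sample_t_matches_pooled_formula(self):
        """Textbook pooled-t oracle on a design of group indicators only."""
        rng = np.random.default_rng(7)
        x, y = rng.normal(1.0, 1.0, 10), rng.normal(0.0, 1.0, 10)
        vals = np.concatenate([x, y])
        maps = [np.full((1, 1, 1), v) for v in vals]
        frame = pd.DataFrame({"PD": [1.0] * 10 + [0.0] * 10, "HC": [0.0] * 10 + [1.0] * 10})
        design = voxel_stats.DesignMatrix(frame=frame, scheme="group_effect")
        fit = fit_glm(maps, design, np.ones((1, 1, 1), bool))
        sm = contrast_t(fit, design.contrast({"PD": 1.0, "HC": -1.0}, tail="greater"))
        t_oracle, _ = stats.ttest_ind(x, y)
        assert sm.peak_t == pytest.approx(t_oracle)
        assert sm.df == 18

    def test_zero_t_maps_to_zero_z(self):
        assert t_to_z(np.array([0.0]), 10)[0] == pytest.approx(0.0, abs=1e-12)

    def test_z_monotone_and_same_peak(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=100) * 3
        z = t_to_z(t, 20)
        order_t = np.argsort(t)
        assert np.all(np.diff(z[order_t]) > 0)
        assert np.argmax(t) == np.argmax(z)

    def test_group_label_exchange_negates_t_map(self):
        subs = _subjects(6, seed=8)
        maps = _null_maps(12, seed=4)
        mask = np.ones((5, 5, 4), bool)
        d1 = build_design(subs)
        swapped = subs.copy()
        swapped["group"] = np.where(subs["group"] == "PD", "HC", "PD")
        d2 = build_design(swapped)
        t1 = contrast_t(fit_glm(maps, d1, mask), d1.contrast({"PD": 1, "HC": -1}))
        t2 = contrast_t(fit_glm(maps, d2, mask), d2.contrast({"PD": 1, "HC": -1}))
        assert np.allclose(t1.t.data, -t2.t.data, equal_nan=True)


class TestPermutation:
    def test_p_value_lower_bound(self):
        subs = _subjects(5, seed=1)
        # inject a giant effect so the observed peak beats every permutation
        maps = []
        for g in subs["group"]:
            base = np.random.default_rng(0).standard_normal((4, 4, 3)) * 0.01
            maps.append(base + (10.0 if g == "PD" else 0.0))
        d = build_design(subs)
        res = permutation_fwe(maps, d, d.contrast({"PD": 1, "HC": -1}, tail="greater"),
                              np.ones((4, 4, 3), bool), n_perm=100, seed=0)
        assert res.p_peak == pytest.approx(1.0 / 101.0)

    def test_min_permutations_enforced(self):
        subs = _subjects(4)
        d = build_design(subs)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_fwe(_null_maps(8), d, d.contrast({"PD": 1, "HC": -1}),
                            np.ones((5, 5, 4), bool), n_perm=50, seed=0)

    def test_null_rejection_rate_calibrated(self):
        """Permutation p-values are valid under the null: rejection at
        alpha = 0.05 stays near nominal over 120 replicates."""
        subs = _subjects(6, seed=2)
        d = build_design(subs)
        c = d.contrast({"PD": 1, "HC": -1}, tail="two")
        mask = np.ones((4, 4, 3), bool)
        rng = np.random.default_rng(55)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            maps = [rng.standard_normal((4, 4, 3)) for _ in range(12)]
            res = permutation_fwe(maps, d, c, mask, n_perm=199, seed=rng)
            rejections += res.p_peak <= 0.05
        rate = rejections / n_rep
        # binomial 99% band around 0.05 for 120 replicates
        assert 0.0 <= rate <= 0.11


class TestSmallVolume:
    def test_single_mask_covering_all_equals_global_fwe(self):
        subs = _subjects(5, seed=3)
        maps = _null_maps(10, seed=6)
        mask = np.ones((5, 5, 4), bool)
        d = build_design(subs)
        c = d.contrast({"PD": 1, "HC": -1}, tail="two")
        global_res = permutation_fwe(maps, d, c, mask, n_perm=200, seed=42)
        svc = small_volume_correct(maps, d, c, {"all": mask}, n_perm=200, seed=42,
                                   bonferroni_across_masks=False)
        assert svc["all"].p_mask == pytest.approx(global_res.p_peak)
        assert svc["all"].peak_t == pytest.approx(
            global_res.stat_map.peak_t if c.tail == "greater" else svc["all"].peak_t
        )

    def test_bonferroni_doubles_p_over_two_masks(self):
        subs = _subjects(5, seed=3)
        maps = _null_maps(10, seed=6)
        m1 = np.zeros((5, 5, 4), bool)
        m2 = np.zeros((5, 5, 4), bool)
        m1[:2], m2[3:] = True, True
        d = build_design(subs)
        c = d.contrast({"PD": 1, "HC": -1}, tail="two")
        raw = small_volume_correct(maps, d, c, {"a": m1, "b": m2}, n_perm=150, seed=1,
                                   bonferroni_across_masks=False)
        adj = small_volume_correct(maps, d, c, {"a": m1, "b": m2}, n_perm=150, seed=1,
                                   bonferroni_across_masks=True)
        for name in ("a", "b"):
            assert adj[name].p_corrected == pytest.approx(min(1.0, 2 * raw[name].p_mask))

    def test_effect_confined_to_one_mask(self):
        """Signal planted only in mask A: significant there, null in B."""
        rng = np.random.default_rng(12)
        subs = _subjects(8, seed=9)
        m1 = np.zeros((6, 5, 4), bool)
        m2 = np.zeros((6, 5, 4), bool)
        m1[:3], m2[3:] = True, True
        maps = []
        for g in subs["group"]:
            m = rng.standard_normal((6, 5, 4))
            if g == "PD":
                m[m1] += 3.0
            maps.append(m)
        d = build_design(subs)
        c = d.contrast({"PD": 1, "HC": -1}, tail="greater")
        svc = small_volume_correct(maps, d, c, {"A": m1, "B": m2}, n_perm=300, seed=5)
        assert svc["A"].p_corrected < 0.05
        assert svc["B"].p_mask > 0.05

    def test_empty_mask_errors(self):
        subs = _subjects(4)
        d = build_design(subs)
        with pytest.raises(ValueError, match="empty"):
            small_volume_correct(_null_maps(8), d, d.contrast({"PD": 1, "HC": -1}),
                                 {"bad": np.zeros((5, 5, 4), bool)}, n_perm=100, seed=0)
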