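"""Synthetic multimodal basal-ganglia phantom with known ground truth.

The phantom emulates the statistical structure a multimodal Parkinson's
disease (PD) imaging analysis assumes, on a common 1 mm grid shared by all
subjects:

* a probabilistic ROI atlas (arbitrary units 0-10) holding four substantia
  nigra (SN) tiers (medial/lateral x left/right) and four putamen
  quadrants (pre-/post-commissural x left/right), symmetric about the
  mid-sagittal plane, plus crus cerebri sphere centers, an occipital
  reference block, and mean GM/WM probability maps;
* a neuromelanin (NM)-sensitive volume whose SN voxel values, after crus
  background subtraction, follow a skew-controllable distribution (shifted
  gamma, moment-matched) whose skewness becomes more negative with disease
  severity;
* a multi-echo gradient-echo magnitude series decaying as
  S(TE) = S0 exp(-R2* TE), with R2* elevated in the LEFT lateral SN only,
  in proportion to severity;
* a dynamic PET frame series exactly consistent with reference-tissue
  Patlak kinetics, C_t = Ki * int C_ref + V * C_ref at the frame-average
  level, with Ki reduced in the putamen (posterior more than anterior) in
  proportion to severity; occipital voxels carry the reference curve
  itself.

A single latent severity d_i in [0, 1] (0 for controls) can drive all
three modality effects jointly ("coupling"), which induces the within-PD
correlations (lower Ki with higher lateral-SN R2*, lower Ki with more
negative skewness) that the interaction analyses test for. Coupling can be
switched off (independent severities per modality) and all effect sizes
can be set to zero for null calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nigra import pet_patlak
from nigra.volumes import ImageVolume, RoiSet, make_sphere_mask

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "PhantomConfig",
    "SubjectRecord",
    "SubjectData",
    "PhantomAtlas",
    "MultimodalDataset",
    "generate_atlas",
    "generate_subject",
    "generate_cohort",
    "write_dataset",
    "draw_skewed_sample",
    "skewed_population_params",
]

SN_ROIS = ("sn_medial_left", "sn_medial_right", "sn_lateral_left", "sn_lateral_right")
PUTAMEN_ROIS = (
    "putamen_anterior_left",
    "putamen_anterior_right",
    "putamen_posterior_left",
    "putamen_posterior_right",
)

#: Printed SN tier volumes (mm^3): left medial, right medial, left lateral,
#: right lateral — the anatomical targets the probabilistic atlas must
#: reproduce after thresholding at 4 a.u.
SN_VOLUMES_MM3 = {
    "sn_medial_left": 164.0,
    "sn_medial_right": 130.0,
    "sn_lateral_left": 137.0,
    "sn_lateral_right": 100.0,
}

#: Putamen quadrant volumes (mm^3) scaled down from anatomical size by 1/8
#: so the four quadrants plus SN fit disjointly on the compact phantom grid
#: while keeping the anatomical ordering (left > right, anterior largest).
PUTAMEN_VOLUMES_MM3 = {
    "putamen_anterior_left": 5356.0 / 8,
    "putamen_anterior_right": 3787.0 / 8,
    "putamen_posterior_left": 5322.0 / 8,
    "putamen_posterior_right": 3203.0 / 8,
}


@dataclass
class EffectSpec:
    """Group effect sizes, expressed as severity-1 (d_i = 1) increments."""

    r2star_hc_sn: float = 30.0  # baseline SN R2*, s^-1
    r2star_pd_latSN_delta: float = 6.0  # max PD increment, left lateral SN, s^-1
    nm_skew_hc: float = 0.0  # target ESNV skewness, controls
    nm_skew_pd: float = -0.6  # target at full severity (more negative)
    ki_putamen_hc: float = 0.012  # baseline putamen Ki, min^-1
    ki_post_delta: float = 0.006  # max reduction, posterior putamen, min^-1
    ki_ant_delta: float = 0.003  # max reduction, anterior putamen, min^-1
    coupling: bool = True  # one latent d_i drives all three modalities

    def __post_init__(self) -> None:
        if self.nm_skew_pd > self.nm_skew_hc:
            raise ValueError("nm_skew_pd must be <= nm_skew_hc")
        if self.ki_putamen_hc - max(self.ki_post_delta, self.ki_ant_delta) < 0:
            raise ValueError("Ki reductions would drive Ki below zero")

    def null(self) -> "EffectSpec":
        """A copy with every group effect switched off."""
        return dataclasses.replace(
            self,
            r2star_pd_latSN_delta=0.0,
            nm_skew_pd=self.nm_skew_hc,
            ki_post_delta=0.0,
            ki_ant_delta=0.0,
        )


@dataclass
class NoiseSpec:
    """Measurement noise plus between-subject biological variability.

    The *_between_sd fields jitter each subject's baseline (SN R2*,
    ESNV-skewness target, putamen Ki) around the population value — the
    spread healthy cohorts show. Without it the control group would have
    (nearly) constant covariates and group-specific slopes would be
    unidentifiable, which no real cohort exhibits."""

    mri_sigma: float = 5.0  # additive SD on MRI magnitudes, a.u.
    pet_cv: float = 0.05  # coefficient of variation on frame activities
    r2star_between_sd: float = 1.0  # s^-1, subject baseline SN R2*
    skew_between_sd: float = 0.08  # subject skewness-target jitter
    ki_between_sd: float = 0.0008  # min^-1, subject baseline putamen Ki

    def __post_init__(self) -> None:
        if any(
            v < 0
            for v in (self.mri_sigma, self.pet_cv, self.r2star_between_sd,
                      self.skew_between_sd, self.ki_between_sd)
        ):
            raise ValueError("noise levels must be >= 0")

    def silent(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class PhantomConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the acquisition the phantom emulates: 1 mm isotropic
    grid, six gradient echoes from 2.3 ms, and the dynamic PET framing
    6x10 s, 8x30 s, 5x120 s, 15x300 s (34 frames, 90 min).
    """

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: float = 1.0
    n_per_group: int = 23
    seed: int = 0
    te_list: tuple[float, ...] = (2.3, 4.6, 6.9, 9.2, 11.5, 13.8)  # ms
    frame_schedule: tuple[tuple[int, float], ...] = ((6, 10.0), (8, 30.0), (5, 120.0), (15, 300.0))
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    flip_fraction: float = 7.0 / 23.0  # PD subjects with right-predominant signs
    roi_volume_scale: float = 1.0  # inflate/deflate every ROI volume
    n_contrasts: int = 1  # multi-echo contrasts generated (PDw[, T1w, MTw])
    # secondary signal parameters (a.u. unless noted)
    nm_background: float = 100.0
    nm_esnv_mean: float = 20.0
    nm_esnv_sd: float = 6.0
    r2star_background: float = 20.0  # s^-1 outside SN
    s0_levels: tuple[float, ...] = (1000.0, 800.0, 600.0)  # per contrast
    ki_background: float = 0.002  # min^-1, non-striatal brain
    v_tissue: float = 0.9
    v_putamen: float = 1.2
    cref_amplitude: float = 80.0  # kBq/mL-scale, arbitrary
    cref_rates_per_min: tuple[float, float] = (0.08, 0.8)  # bi-exponential decay/rise
    crus_sphere_volume_mm3: float = 14.0
    pd_severity_range: tuple[float, float] = (0.25, 1.0)

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 16")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        te = np.asarray(self.te_list, dtype=float)
        if te.size < 2 or np.any(np.diff(te) <= 0) or np.any(te <= 0):
            raise ValueError("te_list must be >= 2 strictly increasing positive echoes")
        if not self.frame_schedule:
            raise ValueError("frame_schedule must not be empty")
        for count, dur in self.frame_schedule:
            if count < 1 or dur <= 0:
                raise ValueError("frame schedule entries must have count >= 1, duration > 0")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")
        if self.n_contrasts < 1 or self.n_contrasts > len(self.s0_levels):
            raise ValueError("n_contrasts out of range")

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with the world origin at the grid center, so the
        mid-sagittal plane is x = 0 and index reversal along axis 0 is the
        left-right mirror."""
        d = self.voxel_size_mm
        aff = np.diag([d, d, d, 1.0])
        aff[:3, 3] = [-(n - 1) / 2.0 * d for n in self.grid_shape]
        return aff

    def schedule(self) -> pet_patlak.FrameSchedule:
        return pet_patlak.build_schedule(list(self.frame_schedule))


@dataclass
class SubjectRecord:
    """One participant's metadata plus the latent ground-truth severities."""

    subject_id: str
    group: str  # "PD" or "HC"
    age: float
    sex: str  # "M" or "F"
    most_affected_side: str = "none"  # "left", "right", "none"
    updrs3: float | None = None
    hy: float | None = None
    duration_years: float | None = None
    ledd: float | None = None
    # latent severities (ground truth, hidden from analyses); with coupling
    # on all three are identical
    d_nm: float = 0.0
    d_r2: float = 0.0
    d_ki: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise ValueError("group must be 'PD' or 'HC'")
        if self.group == "HC":
            if self.most_affected_side != "none":
                raise ValueError("HC subjects have most_affected_side = 'none'")
            if any(v is not None for v in (self.updrs3, self.hy, self.duration_years, self.ledd)):
                raise ValueError("HC subjects carry no clinical scores")
            if any(d != 0.0 for d in (self.d_nm, self.d_r2, self.d_ki)):
                raise ValueError("HC severity must be 0")
        for d in (self.d_nm, self.d_r2, self.d_ki):
            if not 0.0 <= d <= 1.0:
                raise ValueError("severities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# skew-controllable sampling family


def skewed_population_params(skew: float) -> float | None:
    """Gamma shape k = 4/skew^2 matching a target skewness 2/sqrt(k);
    None for (numerically) zero skewness, meaning a normal draw."""
    if abs(skew) < 1e-8:
        return None
    return 4.0 / skew**2


def draw_skewed_sample(
    rng: np.random.Generator, n: int, mean: float, sd: float, skew: float
) -> np.ndarray:
    """Draw n values with population mean/SD/skewness as requested.

    Uses a moment-matched (shifted, optionally sign-reflected) gamma:
    Z = sign(skew) * (G - k) / sqrt(k) with G ~ Gamma(k, 1), k = 4/skew^2,
    has mean 0, variance 1 and skewness exactly ``skew``; the sample is
    mean + sd * Z. Zero skewness falls back to a normal draw.
    """
    k = skewed_population_params(skew)
    if k is None:
        return mean + sd * rng.standard_normal(n)
    g = rng.gamma(k, 1.0, size=n)
    z = (g - k) / np.sqrt(k)
    if skew < 0:
        z = -z
    return mean + sd * z


# ---------------------------------------------------------------------------
# atlas


def _ellipsoid_prob(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm: tuple[float, float, float],
    volume_mm3: float,
    axis_ratios: tuple[float, float, float],
) -> np.ndarray:
    """Probabilistic blob p = 10 (1 - u^2)_+ over an ellipsoid norm u,
    scaled so the p >= 4 region has the requested volume in the continuum."""
    # p >= 4  <=>  u <= c with c = sqrt(0.6)
    c = np.sqrt(0.6)
    ra, rb, rc = axis_ratios
    # continuum volume of {u <= c} is 4/3 pi (a c)(b c)(c_ax c) with a = s*ra ...
    s3 = 3.0 * volume_mm3 / (4.0 * np.pi * c**3 * ra * rb * rc)
    s = s3 ** (1.0 / 3.0)
    semi = np.array([s * ra, s * rb, s * rc])
    idx = np.indices(shape).astype(float)
    org = affine[:3, 3]
    d = affine[0, 0]  # isotropic grid
    xyz = idx * d + org.reshape(3, 1, 1, 1)
    u2 = sum(((xyz[i] - center_mm[i]) / semi[i]) ** 2 for i in range(3))
    return 10.0 * np.clip(1.0 - u2, 0.0, None)


@dataclass
class PhantomAtlas:
    """Probabilistic ROI volumes plus derived ground-truth masks."""

    prob: dict[str, ImageVolume]  # 8 anatomical ROIs, values 0-10 a.u.
    rois: RoiSet  # thresholded anatomical ROIs + crus spheres + occipital
    crus_centers_mm: dict[str, tuple[float, float, float]]
    mean_gm: ImageVolume
    mean_wm: ImageVolume
    brain_mask: np.ndarray

    @property
    def affine(self) -> np.ndarray:
        return self.rois.affine


def generate_atlas(config: PhantomConfig, threshold_au: float = 4.0) -> PhantomAtlas:
    """Build the probabilistic atlas and its ground-truth ROI masks.

    Eight anatomical ROIs (4 SN tiers, 4 putamen quadrants) are placed
    symmetrically about the mid-sagittal plane; thresholding the
    probabilistic volumes at 4 a.u. recovers binary masks whose volumes
    track the printed SN tier volumes. Crus cerebri spheres and an
    occipital reference block are deterministic additions.
    """
    shape = tuple(config.grid_shape)
    aff = config.affine
    scale = config.roi_volume_scale
    lin = scale ** (1.0 / 3.0)  # linear size factor for placement spacing

    # the layout dilates uniformly with the ROI volume scale, so relative
    # geometry (and disjointness) is preserved at any scale
    centers = {
        name: tuple(c * lin for c in center)
        for name, center in {
            "sn_medial_left": (-5.0, -10.0, -6.0),
            "sn_medial_right": (5.0, -10.0, -6.0),
            "sn_lateral_left": (-11.0, -10.0, -6.0),
            "sn_lateral_right": (11.0, -10.0, -6.0),
            "putamen_anterior_left": (-15.0, 8.0, 6.0),
            "putamen_anterior_right": (15.0, 8.0, 6.0),
            "putamen_posterior_left": (-15.0, -9.0, 6.0),
            "putamen_posterior_right": (15.0, -9.0, 6.0),
        }.items()
    }
    ratios = {name: (1.0, 2.0, 1.2) for name in SN_ROIS}
    ratios.update({name: (1.0, 1.6, 1.3) for name in PUTAMEN_ROIS})
    volumes = {**SN_VOLUMES_MM3, **PUTAMEN_VOLUMES_MM3}

    prob: dict[str, ImageVolume] = {}
    for name in SN_ROIS + PUTAMEN_ROIS:
        arr = _ellipsoid_prob(shape, aff, centers[name], volumes[name] * scale, ratios[name])
        prob[name] = ImageVolume(arr, aff.copy())

    masks = {name: vol.data >= threshold_au for name, vol in prob.items()}

    # verify disjoint placement (guards against too-small grids / big scales)
    total = np.zeros(shape, dtype=int)
    for m in masks.values():
        if not m.any():
            raise ValueError("grid too small: an ROI fell entirely outside the grid")
        total += m
    if total.max() > 1:
        raise ValueError("grid too small to place all ROIs disjointly")

    grid_vol = ImageVolume(np.zeros(shape, dtype=np.float32), aff.copy())
    # centers sit on voxel centers (half-integer world mm on an even grid)
    def _snap(v: float) -> float:
        return np.floor(v) + 0.5

    left = tuple(_snap(c * lin) for c in (-8.5, -15.5, -12.5))
    crus_centers = {
        "crus_left": left,
        "crus_right": (-left[0], left[1], left[2]),  # exact mirror
    }
    for name, center in crus_centers.items():
        masks[name] = make_sphere_mask(center, config.crus_sphere_volume_mm3, grid_vol)

    # occipital reference block: a posterior slab
    idx = np.indices(shape).astype(float)
    d = config.voxel_size_mm
    org = aff[:3, 3]
    x = idx[0] * d + org[0]
    y = idx[1] * d + org[1]
    z = idx[2] * d + org[2]
    masks["occipital"] = (
        (np.abs(x) <= 10 * lin)
        & (y >= -(shape[1] - 1) / 2 * d + 2)
        & (y <= -19 * lin)
        & (np.abs(z) <= 7 * lin)
    )

    # brain envelope and mean tissue-probability maps
    semi = np.array([(shape[0] - 4) / 2 * d, (shape[1] - 4) / 2 * d, (shape[2] - 4) / 2 * d])
    u2 = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2
    brain = u2 <= 1.0
    for m in masks.values():  # ROIs always count as brain
        brain |= m
    brain |= brain[::-1]  # mirror-symmetric, so side-flipped maps stay in-brain
    gm = np.where(brain, np.clip(0.6 * (1.0 - 0.4 * u2), 0.3, None), 0.0)
    wm = np.where(brain, 0.25, 0.02)

    rois = RoiSet(masks=masks, affine=aff, provenance={"threshold": threshold_au, "roi_volume_scale": scale})
    return PhantomAtlas(
        prob=prob,
        rois=rois,
        crus_centers_mm=crus_centers,
        mean_gm=ImageVolume(gm, aff.copy()),
        mean_wm=ImageVolume(wm, aff.copy()),
        brain_mask=brain,
    )


# ---------------------------------------------------------------------------
# subject volumes


@dataclass
class SubjectData:
    """All generated volumes and per-voxel ground truth for one subject."""

    record: SubjectRecord
    nm: ImageVolume | None
    multiecho: list  # list of (label, te_list, ImageVolume 4-D)
    pet: ImageVolume | None  # 4-D frames
    true_r2star: ImageVolume
    true_ki: ImageVolume
    true_skew: dict[str, float]  # per SN tier + bilateral targets
    baselines: dict[str, float] | None = None  # subject r2star/ki baselines


def _symmetrized(mask: np.ndarray) -> np.ndarray:
    """Union of a mask with its mid-sagittal mirror (index reversal on the
    left-right axis). Signals are painted on symmetrized regions so that
    side-flipped maps never expose background voxels under the (slightly
    asymmetric) anatomical masks."""
    return mask | mask[::-1]


def _true_r2star_map(
    config: PhantomConfig,
    atlas: PhantomAtlas,
    d_r2: float,
    most_affected_side: str = "left",
    baseline: float | None = None,
) -> np.ndarray:
    """True R2* field: SN tiers at baseline, the lateral tier of the
    affected hemisphere elevated by d_r2 * delta.

    The affected hemisphere follows the record's most_affected_side, so
    that after the analysis-side flip the elevation always lies on the
    LEFT lateral SN. For side "right" the elevated region is the exact
    mirror of the left lateral mask."""
    eff = config.effects
    base = eff.r2star_hc_sn if baseline is None else baseline
    r2 = np.full(config.grid_shape, config.r2star_background)
    sn_sym = _symmetrized(atlas.rois.union(list(SN_ROIS)))
    r2[sn_sym] = base
    lat_left = atlas.rois["sn_lateral_left"]
    elevated = lat_left[::-1] if most_affected_side == "right" else lat_left
    r2[elevated] = base + d_r2 * eff.r2star_pd_latSN_delta
    return r2


def _true_ki_map(
    config: PhantomConfig,
    atlas: PhantomAtlas,
    d_ki: float,
    baseline: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    eff = config.effects
    base = eff.ki_putamen_hc if baseline is None else baseline
    ki = np.where(atlas.brain_mask, config.ki_background, 0.0)
    v = np.where(atlas.brain_mask, config.v_tissue, 0.0)
    for kind, delta in (("anterior", eff.ki_ant_delta), ("posterior", eff.ki_post_delta)):
        region = _symmetrized(
            atlas.rois.union([f"putamen_{kind}_left", f"putamen_{kind}_right"])
        )
        ki[region] = max(base - d_ki * delta, 0.0)
        v[region] = config.v_putamen
    occ = atlas.rois["occipital"]
    ki[occ] = 0.0
    v[occ] = 1.0
    return ki, v


def reference_frame_averages(config: PhantomConfig) -> np.ndarray:
    """Analytic frame-averaged reference activities for the bi-exponential
    C_ref(t) = A (exp(-a t) - exp(-b t)), t in minutes."""
    a, b = config.cref_rates_per_min
    A = config.cref_amplitude
    sched = config.schedule()
    t0 = sched.starts_s / 60.0
    t1 = t0 + sched.durations_s / 60.0
    dur = t1 - t0
    integ = (np.exp(-a * t0) - np.exp(-a * t1)) / a - (np.exp(-b * t0) - np.exp(-b * t1)) / b
    return A * integ / dur


ALL_MODALITIES = ("nm", "mri", "pet")


def generate_subject(
    config: PhantomConfig,
    record: SubjectRecord,
    rng: np.random.Generator,
    atlas: PhantomAtlas | None = None,
    modalities: tuple[str, ...] = ALL_MODALITIES,
) -> SubjectData:
    """Generate the modality volumes and ground truth for one subject.

    The NM SN voxels are drawn iid from the skew family at the subject's
    target skewness (so every SN sub-ROI, unilateral or pooled bilateral,
    shares that population skewness). The skew family describes the
    MEASURED voxel distribution — acquisition noise is part of the
    distribution being characterized — so mri_sigma noise is added to the
    NM background and crus but not on top of the SN draw. The multi-echo
    series decays mono-exponentially at the subject's true R2*; PET
    frames are exactly Patlak-consistent at the subject's true Ki before
    noise. ``modalities`` restricts generation (calibration studies often
    need a single modality); omitted modalities are None on the result.
    """
    if atlas is None:
        atlas = generate_atlas(config)
    unknown = set(modalities) - set(ALL_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}")
    eff, noise = config.effects, config.noise
    shape = tuple(config.grid_shape)
    aff = config.affine

    # subject baselines are drawn FIRST, so they do not depend on which
    # modalities are generated afterwards
    r2_baseline = eff.r2star_hc_sn + noise.r2star_between_sd * rng.standard_normal()
    skew_jitter = noise.skew_between_sd * rng.standard_normal()
    ki_baseline = max(
        eff.ki_putamen_hc + noise.ki_between_sd * rng.standard_normal(),
        max(eff.ki_post_delta, eff.ki_ant_delta),
    )

    target_skew = (
        eff.nm_skew_hc + record.d_nm * (eff.nm_skew_pd - eff.nm_skew_hc) + skew_jitter
    )
    true_skew = {name: target_skew for name in SN_ROIS}
    true_skew["sn_lateral_bilateral"] = target_skew
    true_skew["sn_medial_bilateral"] = target_skew
    true_skew["sn_bilateral"] = target_skew

    nm_vol = None
    if "nm" in modalities:
        nm = np.full(shape, config.nm_background)
        if noise.mri_sigma > 0:
            nm = nm + noise.mri_sigma * rng.standard_normal(shape)
        sn_region = _symmetrized(atlas.rois.union(list(SN_ROIS)))
        n_sn = int(sn_region.sum())
        esnv = draw_skewed_sample(rng, n_sn, config.nm_esnv_mean, config.nm_esnv_sd, target_skew)
        nm[sn_region] = config.nm_background + esnv
        nm_vol = ImageVolume(nm, aff.copy())

    r2_map = _true_r2star_map(
        config, atlas, record.d_r2, record.most_affected_side, baseline=r2_baseline
    )
    series = []
    if "mri" in modalities:
        te = np.asarray(config.te_list, dtype=float)  # ms
        decay = np.exp(-r2_map[..., None] * (te / 1000.0))  # R2* in s^-1, TE in ms
        labels = ("PDw", "T1w", "MTw")
        for c in range(config.n_contrasts):
            s = config.s0_levels[c] * decay
            if noise.mri_sigma > 0:
                s = s + noise.mri_sigma * rng.standard_normal(s.shape)
            series.append((labels[c], tuple(te), ImageVolume(s, aff.copy())))

    ki_arr, v_arr = _true_ki_map(config, atlas, record.d_ki, baseline=ki_baseline)
    pet_vol = None
    if "pet" in modalities:
        sched = config.schedule()
        R = reference_frame_averages(config)  # (n_frames,)
        X = pet_patlak.reference_running_integral(R, sched.mid_times_min)
        pet = ki_arr[..., None] * X[None, None, None, :] + v_arr[..., None] * R[None, None, None, :]
        if noise.pet_cv > 0:
            pet = pet * (1.0 + noise.pet_cv * rng.standard_normal(pet.shape))
            pet = np.clip(pet, 0.0, None)
        pet_vol = ImageVolume(pet, aff.copy())

    return SubjectData(
        record=record,
        nm=nm_vol,
        multiecho=series,
        pet=pet_vol,
        true_r2star=ImageVolume(r2_map, aff.copy()),
        true_ki=ImageVolume(ki_arr, aff.copy()),
        true_skew=true_skew,
        baselines={"r2star": r2_baseline, "ki": ki_baseline},
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class MultimodalDataset:
    config: PhantomConfig
    atlas: PhantomAtlas
    subjects: list[SubjectRecord]
    data: dict[str, SubjectData]  # subject_id -> volumes
    ground_truth: pd.DataFrame

    def subject(self, subject_id: str) -> SubjectData:
        return self.data[subject_id]


def _make_records(config: PhantomConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    n = config.n_per_group
    records: list[SubjectRecord] = []
    lo, hi = config.pd_severity_range
    n_flip = int(round(config.flip_fraction * n))
    sides = np.array(["right"] * n_flip + ["left"] * (n - n_flip))
    rng.shuffle(sides)
    for g, group in (("pd", "PD"), ("hc", "HC")):
        for i in range(n):
            age = float(np.clip(rng.normal(67.5, 9.8), 40, 90))
            sex = "M" if rng.random() < 0.5 else "F"
            if group == "PD":
                d = float(rng.uniform(lo, hi))
                if config.effects.coupling:
                    d_nm = d_r2 = d_ki = d
                else:
                    d_nm = float(rng.uniform(lo, hi))
                    d_r2 = float(rng.uniform(lo, hi))
                    d_ki = float(rng.uniform(lo, hi))
                records.append(
                    SubjectRecord(
                        subject_id=f"{g}{i+1:03d}",
                        group=group,
                        age=age,
                        sex=sex,
                        most_affected_side=str(sides[i]),
                        updrs3=float(np.clip(10 + 40 * d + rng.normal(0, 5), 5, 80)),
                        hy=float(np.clip(round((1 + 2 * d) * 2) / 2, 1, 3)),
                        duration_years=float(np.clip(1 + 10 * d + rng.normal(0, 2), 0.5, 20)),
                        ledd=float(np.clip(820 * d + rng.normal(0, 120), 0, 1500)),
                        d_nm=d_nm,
                        d_r2=d_r2,
                        d_ki=d_ki,
                    )
                )
            else:
                records.append(
                    SubjectRecord(subject_id=f"{g}{i+1:03d}", group=group, age=age, sex=sex)
                )
    return records


def generate_cohort(
    config: PhantomConfig, modalities: tuple[str, ...] = ALL_MODALITIES
) -> MultimodalDataset:
    """Generate the full multimodal cohort, reproducibly from config.seed.

    One master seed spawns independent child streams for the roster and
    for each subject's volumes, so per-subject data do not depend on the
    cohort size ordering.
    """
    ss = np.random.SeedSequence(config.seed)
    roster_rng = np.random.default_rng(ss.spawn(1)[0])
    atlas = generate_atlas(config)
    records = _make_records(config, roster_rng)
    child_seeds = ss.spawn(len(records) + 1)[1:]
    data: dict[str, SubjectData] = {}
    gt_rows = []
    for rec, child in zip(records, child_seeds):
        rng = np.random.default_rng(child)
        sub = generate_subject(config, rec, rng, atlas=atlas, modalities=modalities)
        data[rec.subject_id] = sub
        eff = config.effects
        # "lat" is the affected lateral SN tier (left after side-flipping)
        gt_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "d_nm": rec.d_nm,
                "d_r2": rec.d_r2,
                "d_ki": rec.d_ki,
                "true_skew_sn": sub.true_skew["sn_bilateral"],
                "true_r2star_lat": sub.baselines["r2star"]
                + rec.d_r2 * eff.r2star_pd_latSN_delta,
                "true_ki_post": sub.baselines["ki"] - rec.d_ki * eff.ki_post_delta,
                "true_ki_ant": sub.baselines["ki"] - rec.d_ki * eff.ki_ant_delta,
            }
        )
    return MultimodalDataset(
        config=config,
        atlas=atlas,
        subjects=records,
        data=data,
        ground_truth=pd.DataFrame(gt_rows),
    )


# ---------------------------------------------------------------------------
# on-disk layout

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "most_affected_side",
    "updrs3",
    "hy",
    "duration_years",
    "ledd",
]


def subject_table(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in SUBJECT_COLUMNS})
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def write_dataset(dataset: MultimodalDataset, directory: str | Path) -> None:
    """Write the cohort as NIfTI volumes plus tab-separated tables.

    Layout: ``atlas/`` probabilistic maps and masks, ``sub-<id>/`` per
    subject with nm.nii, multiecho_<label>.nii (+ te YAML sidecar),
    pet.nii (+ schedule YAML sidecar), and top-level subjects.tsv /
    ground_truth.tsv.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    atlas_dir = directory / "atlas"
    atlas_dir.mkdir(exist_ok=True)
    for name, vol in dataset.atlas.prob.items():
        vol.save(atlas_dir / f"prob_{name}.nii")
    dataset.atlas.rois.save(atlas_dir)
    dataset.atlas.mean_gm.save(atlas_dir / "mean_gm.nii")
    dataset.atlas.mean_wm.save(atlas_dir / "mean_wm.nii")

    subject_table(dataset.subjects).to_csv(directory / "subjects.tsv", sep="\t", index=False)
    dataset.ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    with open(directory / "schedule.yaml", "w") as fh:
        yaml.safe_dump([[int(c), float(d)] for c, d in dataset.config.frame_schedule], fh)

    for rec in dataset.subjects:
        sub = dataset.data[rec.subject_id]
        sdir = directory / f"sub-{rec.subject_id}"
        sdir.mkdir(exist_ok=True)
        if sub.nm is not None:
            sub.nm.save(sdir / "nm.nii")
        for label, te, vol in sub.multiecho:
            vol.save(sdir / f"multiecho_{label}.nii")
            with open(sdir / f"multiecho_{label}_te_ms.yaml", "w") as fh:
                yaml.safe_dump([float(t) for t in te], fh)
        if sub.pet is not None:
            sub.pet.save(sdir / "pet.nii")
        sub.true_r2star.save(sdir / "true_r2star.nii")
        sub.true_ki.save(sdir / "true_ki.nii")
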