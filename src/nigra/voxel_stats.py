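"""Voxelwise general linear models with permutation-based FWE inference.

Group effects, clinical regressions, and group-by-covariate interactions
are all expressed as one GLM per voxel, Y_v = X beta_v + e_v, with a
design shared across voxels. Family-wise error over the search mask is
controlled by max-statistic permutation: nuisance covariates (age, sex,
and any common-slope term) are handled by the Freedman-Lane scheme, which
permutes the residuals of the reduced (nuisance-only) model and carries
the nuisance fit along. The corrected peak p-value is

    p = (1 + #{permutation max >= observed peak}) / (1 + n_perm)

and small-volume correction restricts the max statistic to an anatomical
mask, optionally Bonferroni-scaled across the masks tested.

This permutation machinery replaces parametric random-field-theory
inference: it is exact under exchangeability and needs no smoothness
estimate, which suits the compact phantom grids this package analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from nigra.volumes import ImageVolume

__all__ = [
    "DesignMatrix",
    "Contrast",
    "GlmFit",
    "StatMap",
    "PermutationResult",
    "build_design",
    "fit_glm",
    "contrast_t",
    "permutation_fwe",
    "small_volume_correct",
    "t_to_z",
]


@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with named columns.

    ``group_effect`` scheme: [PD, HC, age, sex]; ``group_by_covariate``
    adds group-specific slopes [cov_PD, cov_HC] of a grand-mean-centered
    covariate. Group indicators double as per-group intercepts.
    """

    frame: pd.DataFrame
    scheme: str
    covariate_name: str | None = None

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    def contrast(self, weights: dict[str, float], tail: str = "two", description: str = "") -> "Contrast":
        """Build a contrast from a {column: weight} mapping."""
        w = np.zeros(len(self.frame.columns))
        for name, value in weights.items():
            w[self.frame.columns.get_loc(name)] = value
        return Contrast(weights=w, tail=tail, description=description or str(weights))


@dataclass
class Contrast:
    weights: np.ndarray
    tail: str = "two"  # "two" or "greater" (one-tailed on c'beta > 0)
    description: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights):
            raise ValueError("contrast is all-zero")
        if self.tail not in ("two", "greater"):
            raise ValueError("tail must be 'two' or 'greater'")


def build_design(
    subjects: pd.DataFrame,
    covariate: np.ndarray | str | None = None,
    scheme: str = "group_effect",
) -> DesignMatrix:
    """Assemble the voxelwise design from a subject table.

    ``subjects`` needs columns group ("PD"/"HC"), age, sex ("M"/"F").
    For ``group_by_covariate``, ``covariate`` supplies one scalar per
    subject (array, or the name of a column); it is centered to zero mean
    over ALL subjects before being split into group-specific columns.
    """
    if scheme not in ("group_effect", "group_by_covariate"):
        raise ValueError(f"unknown scheme {scheme!r}")
    group = subjects["group"].to_numpy()
    pd_ind = (group == "PD").astype(float)
    hc_ind = (group == "HC").astype(float)
    age = subjects["age"].to_numpy(dtype=float)
    sex = np.where(subjects["sex"].to_numpy() == "M", 0.5, -0.5)
    cols = {
        "PD": pd_ind,
        "HC": hc_ind,
        "age": age - age.mean(),
        "sex": sex - sex.mean(),
    }
    cov_name = None
    if scheme == "group_by_covariate":
        if covariate is None:
            raise ValueError("group_by_covariate requires a covariate")
        if isinstance(covariate, str):
            cov_name = covariate
            cov = subjects[covariate].to_numpy(dtype=float)
        else:
            cov_name = "covariate"
            cov = np.asarray(covariate, dtype=float)
        if cov.size != len(subjects):
            raise ValueError("covariate length does not match the subject table")
        if np.any(~np.isfinite(cov)):
            raise ValueError("covariate contains non-finite values")
        cov = cov - cov.mean()
        cols[f"{cov_name}_PD"] = cov * pd_ind
        cols[f"{cov_name}_HC"] = cov * hc_ind
    frame = pd.DataFrame(cols)
    X = frame.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j, name in enumerate(frame.columns):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame=frame, scheme=scheme, covariate_name=cov_name)


@dataclass
class GlmFit:
    beta: np.ndarray  # (p, n_vox)
    sigma2: np.ndarray  # (n_vox,) residual variance
    df: int
    design: DesignMatrix
    mask: np.ndarray
    affine: np.ndarray
    xtx_inv: np.ndarray


def _stack_maps(maps, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject volumes into (n_subjects, n_mask_voxels)."""
    arrays = []
    affine = None
    for m in maps:
        if isinstance(m, ImageVolume):
            if affine is None:
                affine = m.affine
            arrays.append(m.data[mask])
        else:
            arrays.append(np.asarray(m)[mask])
    if affine is None:
        affine = np.eye(4)
    return np.stack(arrays, axis=0), affine


def fit_glm(maps, design: DesignMatrix, analysis_mask: np.ndarray) -> GlmFit:
    """Voxelwise OLS of per-subject maps on the design, within a mask."""
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if not analysis_mask.any():
        raise ValueError("analysis mask is empty")
    Y, affine = _stack_maps(maps, analysis_mask)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("one map per design row is required")
    if not np.all(np.isfinite(Y)):
        raise ValueError(
            "maps contain non-finite values inside the analysis mask; "
            "restrict the mask to fitted voxels"
        )
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer subjects than design columns")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / df
    return GlmFit(
        beta=beta,
        sigma2=sigma2,
        df=df,
        design=design,
        mask=analysis_mask,
        affine=affine,
        xtx_inv=np.linalg.pinv(X.T @ X),
    )


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Probit transform of the t CDF: Z = Phi^-1(F_t(t, df)), computed
    tail-wise for numerical stability; strictly monotone in t."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], df))
    return z


@dataclass
class StatMap:
    """Voxelwise t/Z maps for one contrast, with peak metadata."""

    t: ImageVolume
    z: ImageVolume
    df: int
    contrast: Contrast
    mask: np.ndarray
    peak_ijk: tuple[int, int, int]
    peak_world_mm: tuple[float, float, float]
    peak_t: float
    peak_z: float
    corrected_p: float | None = None
    inference: dict = field(default_factory=dict)


def _t_stats(Y: np.ndarray, X: np.ndarray, pinv: np.ndarray, c: np.ndarray,
             cvar: float, df: int) -> np.ndarray:
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    num = c @ beta
    den = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    return num / den


def contrast_t(fit: GlmFit, contrast: Contrast) -> StatMap:
    """t = c'beta / sqrt(sigma2 c'(X'X)^-1 c) and its Z transform."""
    c = contrast.weights
    if c.size != fit.beta.shape[0]:
        raise ValueError("contrast length does not match the design")
    cvar = float(c @ fit.xtx_inv @ c)
    num = c @ fit.beta
    t_vals = num / np.sqrt(np.maximum(fit.sigma2 * cvar, 1e-300))
    z_vals = t_to_z(t_vals, fit.df)
    stat = t_vals if contrast.tail == "greater" else np.abs(t_vals)
    peak_flat = int(np.argmax(stat))
    mask_idx = np.argwhere(fit.mask)
    peak_ijk = tuple(int(v) for v in mask_idx[peak_flat])
    world = (fit.affine[:3, :3] @ np.array(peak_ijk, dtype=float) + fit.affine[:3, 3])
    shape = fit.mask.shape
    t_arr = np.full(shape, np.nan)
    z_arr = np.full(shape, np.nan)
    t_arr[fit.mask] = t_vals
    z_arr[fit.mask] = z_vals
    return StatMap(
        t=ImageVolume(t_arr, fit.affine.copy()),
        z=ImageVolume(z_arr, fit.affine.copy()),
        df=fit.df,
        contrast=contrast,
        mask=fit.mask,
        peak_ijk=peak_ijk,
        peak_world_mm=tuple(float(v) for v in world),
        peak_t=float(t_vals[peak_flat]),
        peak_z=float(z_vals[peak_flat]),
    )


def _partition_nuisance(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Nuisance block for Freedman-Lane: all zero-weight columns plus the
    contrast's null-space combinations of the columns of interest."""
    interest = np.flatnonzero(c)
    others = np.flatnonzero(c == 0)
    blocks = [X[:, others]] if others.size else []
    ci = c[interest]
    null = linalg.null_space(ci[None, :])
    if null.size:
        blocks.append(X[:, interest] @ null)
    if not blocks:
        return np.zeros((X.shape[0], 0))
    return np.concatenate(blocks, axis=1)


@dataclass
class PermutationResult:
    stat_map: StatMap
    p_peak: float
    fwe_p: ImageVolume
    perm_max: np.ndarray
    n_perm: int


def _freedman_lane(
    Y: np.ndarray,
    X: np.ndarray,
    contrast: Contrast,
    n_perm: int,
    rng: np.random.Generator,
    submask_cols: dict[str, np.ndarray] | None = None,
):
    """Observed t plus the permutation max-statistic distribution(s).

    ``submask_cols`` optionally maps names to boolean column selectors of
    Y; the per-permutation max is recorded within each selection (used by
    small-volume correction). Returns (t_obs, {name: (n_perm,) maxima}).
    """
    n, p = X.shape
    c = contrast.weights
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.pinv(X.T @ X)
    cvar = float(c @ xtx_inv @ c)
    df = n - np.linalg.matrix_rank(X)

    Z = _partition_nuisance(X, c)
    if Z.shape[1]:
        gamma = np.linalg.pinv(Z) @ Y
        fitted = Z @ gamma
    else:
        fitted = np.zeros_like(Y)
    E = Y - fitted  # reduced-model residuals, the exchangeable units

    def statistic(t):
        return t if contrast.tail == "greater" else np.abs(t)

    t_obs = _t_stats(Y, X, pinv, c, cvar, df)
    if submask_cols is None:
        submask_cols = {"__all__": np.ones(Y.shape[1], dtype=bool)}
    maxima = {name: np.empty(n_perm) for name in submask_cols}
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_perm = _t_stats(E[perm] + fitted, X, pinv, c, cvar, df)
        s = statistic(t_perm)
        for name, sel in submask_cols.items():
            maxima[name][b] = s[sel].max()
    return t_obs, maxima, df


def permutation_fwe(
    maps,
    design: DesignMatrix,
    contrast: Contrast,
    mask: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Max-statistic permutation FWE for one contrast over a search mask.

    Freedman-Lane residual shuffling handles nuisance covariates; for a
    group contrast this permutes group assignment relative to the data,
    for a group-specific-slope contrast it permutes the covariate
    relationship. The peak p-value is (1 + #{max >= observed}) / (1 + B),
    never smaller than 1/(1 + B).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    fit = fit_glm(maps, design, mask)
    Y, _ = _stack_maps(maps, mask)
    t_obs, maxima, df = _freedman_lane(Y, design.matrix, contrast, n_perm, rng)
    perm_max = maxima["__all__"]

    stat_obs = t_obs if contrast.tail == "greater" else np.abs(t_obs)
    peak_stat = stat_obs.max()
    p_peak = float((1 + np.sum(perm_max >= peak_stat)) / (1 + n_perm))
    fwe_vals = (1 + (perm_max[None, :] >= stat_obs[:, None]).sum(axis=1)) / (1 + n_perm)

    stat_map = contrast_t(fit, contrast)
    stat_map.corrected_p = p_peak
    stat_map.inference = {"method": "max-statistic permutation (Freedman-Lane)",
                          "n_perm": n_perm, "mask_voxels": int(mask.sum())}
    fwe_arr = np.full(mask.shape, np.nan)
    fwe_arr[mask] = fwe_vals
    return PermutationResult(
        stat_map=stat_map,
        p_peak=p_peak,
        fwe_p=ImageVolume(fwe_arr, fit.affine.copy()),
        perm_max=perm_max,
        n_perm=n_perm,
    )


@dataclass
class SvcPeak:
    mask_name: str
    peak_world_mm: tuple[float, float, float]
    peak_t: float
    peak_z: float
    p_mask: float  # FWE within the mask
    p_corrected: float  # after the across-mask Bonferroni factor


def small_volume_correct(
    maps,
    design: DesignMatrix,
    contrast: Contrast,
    svc_masks: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    bonferroni_across_masks: bool = True,
) -> dict[str, SvcPeak]:
    """Permutation FWE with the max statistic restricted to each small
    anatomical mask, sharing one permutation pass across masks.

    With ``bonferroni_across_masks`` the within-mask corrected p is
    multiplied by the number of masks (capped at 1), controlling the type
    I error over the family of masks tested.
    """
    if not svc_masks:
        raise ValueError("no SVC masks given")
    for name, m in svc_masks.items():
        if not np.asarray(m, dtype=bool).any():
            raise ValueError(f"SVC mask {name!r} is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    union = np.zeros(next(iter(svc_masks.values())).shape, dtype=bool)
    for m in svc_masks.values():
        union |= np.asarray(m, dtype=bool)
    fit = fit_glm(maps, design, union)
    Y, affine = _stack_maps(maps, union)

    # boolean column selectors of Y (which is ordered by union's C-order)
    flat_union = np.flatnonzero(union.reshape(-1))
    selectors = {}
    for name, m in svc_masks.items():
        sel = np.isin(flat_union, np.flatnonzero(np.asarray(m, dtype=bool).reshape(-1)))
        selectors[name] = sel

    t_obs, maxima, df = _freedman_lane(Y, design.matrix, contrast, n_perm, rng, selectors)
    stat_obs = t_obs if contrast.tail == "greater" else np.abs(t_obs)
    factor = len(svc_masks) if bonferroni_across_masks else 1
    results: dict[str, SvcPeak] = {}
    union_idx = np.argwhere(union)
    for name, sel in selectors.items():
        stat_in = stat_obs[sel]
        j = int(np.argmax(stat_in))
        peak_stat = float(stat_in[j])
        p_mask = float((1 + np.sum(maxima[name] >= peak_stat)) / (1 + n_perm))
        # locate the peak voxel inside the mask
        ijk = union_idx[np.flatnonzero(sel)[j]]
        world = affine[:3, :3] @ ijk.astype(float) + affine[:3, 3]
        t_val = float(t_obs[sel][j])
        results[name] = SvcPeak(
            mask_name=name,
            peak_world_mm=tuple(float(v) for v in world),
            peak_t=t_val,
            peak_z=float(t_to_z(np.array([t_val]), df)[0]),
            p_mask=p_mask,
            p_corrected=min(1.0, factor * p_mask),
        )
    return results
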