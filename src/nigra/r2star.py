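"""Voxelwise R2* estimation from multi-echo gradient-echo magnitudes.

The magnitude of a gradient-echo acquisition decays mono-exponentially
with echo time, S(TE) = S0 exp(-R2* TE), so ordinary least squares of
ln S on TE gives -R2* as the slope. When several differently weighted
contrasts (PDw/T1w/MTw) of a multiparameter-mapping protocol are
available, a joint fit shares one decay slope across contrasts with a
separate intercept each (the ESTATICS pooling idea), which is noticeably
more precise than fitting each contrast alone.

Echo times are supplied in ms and R2* is reported in s^-1; the unit
conversion is explicit in the fit. Fits are unweighted in the log domain
(no Rician weighting), which is accurate in the high-SNR regime the
phantom emulates.

A quality-control regression relates region-median R2* to post-mortem
regional brain iron concentrations; a reference table of the classic
adult iron values (mg Fe / 100 g fresh weight, after Hallgren &
Sourander) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from nigra.volumes import ImageVolume

__all__ = [
    "MultiEchoSeries",
    "R2StarMap",
    "fit_r2star_loglinear",
    "fit_r2star_estatics",
    "iron_calibration_regression",
    "load_iron_reference_table",
]

#: relative signal floor applied before the log transform
SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass
class MultiEchoSeries:
    """A 4-D magnitude series (last axis = echo) with its echo times (ms)."""

    volume: ImageVolume
    te_ms: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.volume.data.ndim != 4:
            raise ValueError("multi-echo series must be 4-D")
        if self.te_ms.size != self.volume.data.shape[-1]:
            raise ValueError("echo count does not match te_ms")
        if self.te_ms.size < 2:
            raise ValueError("need at least 2 echoes")
        if np.any(self.te_ms <= 0) or np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")


@dataclass
class R2StarMap:
    r2star: ImageVolume  # s^-1
    s0: ImageVolume | list[ImageVolume]  # a.u., extrapolated signal at TE = 0
    residual_var: ImageVolume  # log-domain residual variance
    flagged: np.ndarray  # voxels where any echo hit the signal floor


def _prepare_log_signal(data: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp non-positive signal to a floor, log, and flag clamped voxels."""
    sig = data[mask].astype(float)  # (n_vox, n_echo)
    floor = SIGNAL_FLOOR_FRACTION * max(float(np.nanmax(data)), 1.0)
    clamped = sig < floor
    sig = np.where(clamped, floor, sig)
    return np.log(sig), clamped.any(axis=1)


def fit_r2star_loglinear(series: MultiEchoSeries, mask: np.ndarray | None = None) -> R2StarMap:
    """Per-voxel OLS of ln S against TE; slope = -R2*.

    Exact on noiseless mono-exponential data. Voxels with any non-positive
    echo are clamped to a relative floor and flagged.
    """
    data = series.volume.data
    shape = data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask grid does not match the series")
    log_s, flagged_vox = _prepare_log_signal(data, mask)
    te_s = series.te_ms / 1000.0
    X = np.column_stack([np.ones_like(te_s), -te_s])
    coef, *_ = np.linalg.lstsq(X, log_s.T, rcond=None)  # (2, n_vox)
    resid = log_s.T - X @ coef
    dof = max(te_s.size - 2, 1)
    rvar = (resid**2).sum(axis=0) / dof

    r2_arr = np.full(shape, np.nan)
    s0_arr = np.full(shape, np.nan)
    rv_arr = np.full(shape, np.nan)
    flag_arr = np.zeros(shape, dtype=bool)
    r2_arr[mask] = coef[1]
    s0_arr[mask] = np.exp(coef[0])
    rv_arr[mask] = rvar
    flag_arr[mask] = flagged_vox
    aff = series.volume.affine
    return R2StarMap(
        r2star=ImageVolume(r2_arr, aff.copy()),
        s0=ImageVolume(s0_arr, aff.copy()),
        residual_var=ImageVolume(rv_arr, aff.copy()),
        flagged=flag_arr,
    )


def fit_r2star_estatics(
    series_list: list[MultiEchoSeries], mask: np.ndarray | None = None
) -> R2StarMap:
    """Joint log-linear fit of several contrasts with one shared R2* slope
    and a per-contrast intercept (ESTATICS-style pooling).

    With a single contrast this reduces exactly to
    :func:`fit_r2star_loglinear`.
    """
    if not series_list:
        raise ValueError("need at least one series")
    shape = series_list[0].volume.data.shape[:3]
    for s in series_list:
        if s.volume.data.shape[:3] != shape:
            raise ValueError("series grids differ")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    m = len(series_list)
    logs, flags = [], []
    te_blocks, design_blocks = [], []
    for j, s in enumerate(series_list):
        log_s, fl = _prepare_log_signal(s.volume.data, mask)
        logs.append(log_s)
        flags.append(fl)
        te_s = s.te_ms / 1000.0
        block = np.zeros((te_s.size, m + 1))
        block[:, 0] = -te_s
        block[:, 1 + j] = 1.0
        design_blocks.append(block)
        te_blocks.append(te_s)
    Y = np.concatenate(logs, axis=1).T  # (sum_echoes, n_vox)
    X = np.concatenate(design_blocks, axis=0)  # (sum_echoes, 1+m)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    rvar = (resid**2).sum(axis=0) / dof

    aff = series_list[0].volume.affine
    r2_arr = np.full(shape, np.nan)
    r2_arr[mask] = coef[0]
    rv_arr = np.full(shape, np.nan)
    rv_arr[mask] = rvar
    s0_maps = []
    for j in range(m):
        s0_arr = np.full(shape, np.nan)
        s0_arr[mask] = np.exp(coef[1 + j])
        s0_maps.append(ImageVolume(s0_arr, aff.copy()))
    flag_arr = np.zeros(shape, dtype=bool)
    flag_arr[mask] = np.any(flags, axis=0)
    return R2StarMap(
        r2star=ImageVolume(r2_arr, aff.copy()),
        s0=s0_maps if m > 1 else s0_maps[0],
        residual_var=ImageVolume(rv_arr, aff.copy()),
        flagged=flag_arr,
    )


def load_iron_reference_table() -> pd.DataFrame:
    """Adult regional brain iron concentrations (mg Fe / 100 g fresh
    weight), after the classic post-mortem series of Hallgren & Sourander
    (J Neurochem, 1958). Columns: region, iron_mg_per_100g."""
    with resources.files("nigra.data").joinpath("hallgren_iron.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def iron_calibration_regression(table: pd.DataFrame) -> tuple[float, float, float]:
    """Simple linear regression of region-median R2* on iron concentration.

    ``table`` needs columns ``iron_mg_per_100g`` and ``r2star``; returns
    (slope, intercept, R^2). The coefficient of determination quantifies
    how much of the regional R2* variation iron explains.
    """
    if len(table) < 3:
        raise ValueError("calibration needs at least 3 regions")
    x = np.asarray(table["iron_mg_per_100g"], dtype=float)
    y = np.asarray(table["r2star"], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("iron concentrations are constant")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2
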