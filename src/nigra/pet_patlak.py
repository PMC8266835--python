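"""Reference-tissue Patlak graphical analysis for dynamic PET.

For an irreversibly trapped tracer ([18F]DOPA), the Patlak linearization
with a reference-tissue input reads

    C_t(t) / C_ref(t) = Ki * [ int_0^t C_ref(u) du / C_ref(t) ] + V

so that plotting y(t) = C_t/C_ref against the "stretched time"
x(t) = int C_ref / C_ref yields, beyond an equilibration time t*, a line
whose slope is the influx rate constant Ki (min^-1) and whose intercept V
is an apparent distribution volume ratio.

Frame values are treated throughout as frame-averaged activities (the
integral of the activity over the frame divided by its duration), which is
how scanners report dynamic frames. The running integral of the reference
curve is taken by the trapezoid rule over frame mid-times anchored at
(t=0, C=0); the synthetic phantom uses the identical convention, so the
noiseless phantom is recovered exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from nigra.volumes import ImageVolume

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "PatlakFit",
    "build_schedule",
    "roi_tac",
    "reference_running_integral",
    "patlak_transform",
    "patlak_fit",
    "ki_map",
    "KiMapResult",
]


@dataclass
class FrameSchedule:
    """Contiguous dynamic-PET framing starting at t = 0.

    ``frames`` is an ordered list of (start_s, duration_s) pairs with
    start_{k+1} = start_k + duration_k.
    """

    frames: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty frame schedule")
        t = 0.0
        for start, dur in self.frames:
            if dur <= 0:
                raise ValueError("frame durations must be positive")
            if abs(start - t) > 1e-9:
                raise ValueError("frames must be contiguous and start at 0")
            t += dur

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.starts_s[-1] + self.durations_s[-1])


@dataclass
class TimeActivityCurve:
    """Mean regional activity per frame, indexed by frame mid-time (min)."""

    mid_times_min: np.ndarray
    activities: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        self.mid_times_min = np.asarray(self.mid_times_min, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.mid_times_min.shape != self.activities.shape:
            raise ValueError("mid-times and activities must have equal length")


@dataclass
class PatlakFit:
    ki: float  # slope, min^-1
    intercept: float  # V, dimensionless
    t_star_min: float
    n_points: int
    residual_sd: float
    used_mid_times_min: np.ndarray = field(default_factory=lambda: np.empty(0))


def build_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Expand a compact (count, duration_s) spec into contiguous frames.

    Example: ``[(6, 10), (8, 30), (5, 120), (15, 300)]`` expands to 34
    frames totalling 90 min.
    """
    if not spec:
        raise ValueError("empty schedule spec")
    frames: list[tuple[float, float]] = []
    t = 0.0
    for count, dur in spec:
        if count < 1:
            raise ValueError("frame counts must be >= 1")
        if dur <= 0:
            raise ValueError("frame durations must be positive")
        for _ in range(int(count)):
            frames.append((t, float(dur)))
            t += float(dur)
    return FrameSchedule(frames=frames)


def roi_tac(pet_series: ImageVolume, mask: np.ndarray, schedule: FrameSchedule,
            region: str = "") -> TimeActivityCurve:
    """Extract a time-activity curve as the per-frame mean over a mask."""
    if pet_series.data.ndim != 4:
        raise ValueError("PET series must be 4-D")
    if pet_series.data.shape[-1] != schedule.n_frames:
        raise ValueError("series frame count does not match the schedule")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pet_series.spatial_shape:
        raise ValueError("mask grid does not match the series")
    if not mask.any():
        raise ValueError("empty mask")
    acts = pet_series.data[mask].mean(axis=0)
    return TimeActivityCurve(schedule.mid_times_min, acts, region=region)


def reference_running_integral(reference: np.ndarray, mid_times_min: np.ndarray) -> np.ndarray:
    """Trapezoid running integral of the reference activity over frame
    mid-times, anchored at (0, 0). Units: activity * min."""
    t = np.concatenate([[0.0], np.asarray(mid_times_min, dtype=float)])
    c = np.concatenate([[0.0], np.asarray(reference, dtype=float)])
    return cumulative_trapezoid(c, t)


def patlak_transform(
    target: TimeActivityCurve, reference: TimeActivityCurve
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map target/reference TACs to Patlak coordinates.

    Returns ``(x, y, mid_times_min)`` restricted to frames where the
    reference activity is positive; x = int C_ref / C_ref (min),
    y = C_t / C_ref (dimensionless). Frames with non-positive reference
    are dropped with a warning.
    """
    if not np.allclose(target.mid_times_min, reference.mid_times_min):
        raise ValueError("target and reference TACs use different schedules")
    ref = reference.activities
    integral = reference_running_integral(ref, reference.mid_times_min)
    good = ref > 0
    if not good.all():
        warnings.warn(f"dropping {int((~good).sum())} frame(s) with non-positive reference")
    x = integral[good] / ref[good]
    y = target.activities[good] / ref[good]
    return x, y, target.mid_times_min[good]


def patlak_fit(
    x: np.ndarray,
    y: np.ndarray,
    mid_times_min: np.ndarray,
    t_star_min: float = 30.0,
    weight_by_duration: np.ndarray | None = None,
) -> PatlakFit:
    """Fit the linear Patlak segment by OLS on frames with mid-time >= t*.

    ``weight_by_duration`` optionally supplies per-frame weights (frame
    durations); the default is unweighted OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(mid_times_min, dtype=float)
    keep = t >= t_star_min
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 frames with mid-time >= t* = {t_star_min} min")
    xs, ys = x[keep], y[keep]
    if weight_by_duration is not None:
        w = np.sqrt(np.asarray(weight_by_duration, dtype=float)[keep])
    else:
        w = np.ones_like(xs)
    A = np.column_stack([xs, np.ones_like(xs)]) * w[:, None]
    coef, *_ = np.linalg.lstsq(A, ys * w, rcond=None)
    resid = ys - (coef[0] * xs + coef[1])
    dof = max(len(xs) - 2, 1)
    return PatlakFit(
        ki=float(coef[0]),
        intercept=float(coef[1]),
        t_star_min=float(t_star_min),
        n_points=int(keep.sum()),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        used_mid_times_min=t[keep],
    )


@dataclass
class KiMapResult:
    ki: ImageVolume  # min^-1
    intercept: ImageVolume  # V
    t_star_min: float
    n_points: int
    reference: TimeActivityCurve


def ki_map(
    pet_series: ImageVolume,
    reference_mask: np.ndarray,
    schedule: FrameSchedule,
    t_star_min: float = 30.0,
    brain_mask: np.ndarray | None = None,
) -> KiMapResult:
    """Voxelwise Patlak Ki map sharing a single reference-region TAC.

    Voxels outside ``brain_mask`` (or where the fit fails) are set to NaN.
    """
    ref = roi_tac(pet_series, reference_mask, schedule, region="reference")
    if not np.any(ref.activities > 0):
        raise ValueError("reference TAC is not positive anywhere")
    good = ref.activities > 0
    if not good.all():
        warnings.warn(f"dropping {int((~good).sum())} frame(s) with non-positive reference")
    t = schedule.mid_times_min
    integral = reference_running_integral(ref.activities, t)
    x = integral[good] / ref.activities[good]
    tg = t[good]
    keep = tg >= t_star_min
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 frames with mid-time >= t* = {t_star_min} min")

    shape = pet_series.spatial_shape
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)

    frames = pet_series.data[brain_mask][:, good][:, keep]  # (n_vox, n_used)
    y = frames / ref.activities[good][keep]
    A = np.column_stack([x[keep], np.ones(int(keep.sum()))])
    coef, *_ = np.linalg.lstsq(A, y.T, rcond=None)  # (2, n_vox)

    ki_arr = np.full(shape, np.nan)
    v_arr = np.full(shape, np.nan)
    ki_vals = coef[0].copy()
    v_vals = coef[1].copy()
    bad = ~np.isfinite(ki_vals)
    ki_vals[bad] = np.nan
    v_vals[bad] = np.nan
    ki_arr[brain_mask] = ki_vals
    v_arr[brain_mask] = v_vals
    return KiMapResult(
        ki=ImageVolume(ki_arr, pet_series.affine.copy()),
        intercept=ImageVolume(v_arr, pet_series.affine.copy()),
        t_star_min=float(t_star_min),
        n_points=int(keep.sum()),
        reference=ref,
    )
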