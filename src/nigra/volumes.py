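"""Volume I/O, mask construction, side-flipping, and smoothing.

All spatial data is carried by :class:`ImageVolume`, a scalar grid plus a
4x4 voxel-to-world affine (mm, RAS+). Masks live in :class:`RoiSet`, a
named collection of boolean arrays over a shared grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "RoiSet",
    "threshold_probabilistic_atlas",
    "make_sphere_mask",
    "build_gm_mask",
    "flip_lateralized",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: FWHM / sigma ratio of a Gaussian, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return float(fwhm) / FWHM_PER_SIGMA


@dataclass
class ImageVolume:
    """A 3-D scalar grid (or 4-D series) with a voxel-to-world affine.

    Parameters
    ----------
    data:
        3-D array, or 4-D with the last axis indexing echoes/frames.
    affine:
        4x4 voxel-to-world transform in mm (RAS+ orientation). The same
        spatial affine applies to every 4-D sub-volume.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3-D or 4-D")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n x 3) to world mm coordinates (n x 3)."""
        ijk = np.atleast_2d(ijk).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.dataobj), affine=img.affine)


@dataclass
class RoiSet:
    """Named binary masks over a common grid.

    ``provenance`` records how each mask was made (threshold, sphere
    parameters) so downstream tables can report it.
    """

    masks: dict[str, np.ndarray]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        for name, m in self.masks.items():
            self.masks[name] = np.asarray(m, dtype=bool)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid")

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def volume_mm3(self, name: str) -> float:
        vox = float(abs(np.linalg.det(self.affine[:3, :3])))
        return vox * int(self.masks[name].sum())

    def volumes_mm3(self) -> dict[str, float]:
        return {name: self.volume_mm3(name) for name in self.masks}

    def union(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.names
        out = np.zeros_like(next(iter(self.masks.values())), dtype=bool)
        for n in names:
            out |= self.masks[n]
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, m in self.masks.items():
            img = nib.Nifti1Image(m.astype(np.uint8), self.affine)
            nib.save(img, str(directory / f"mask_{name}.nii"))


def threshold_probabilistic_atlas(
    atlas: Mapping[str, ImageVolume] | ImageVolume,
    threshold: float,
) -> RoiSet:
    """Binarize a probabilistic atlas at an intensity threshold.

    A voxel enters a mask iff its probabilistic value is >= ``threshold``
    (inclusive). Pass a mapping of ROI name to probabilistic volume, or a
    single volume (named ``"roi"``).

    Emits a warning for every ROI whose mask comes out empty.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(atlas, ImageVolume):
        atlas = {"roi": atlas}
    masks: dict[str, np.ndarray] = {}
    affine = None
    for name, vol in atlas.items():
        if affine is None:
            affine = vol.affine
        if np.any(vol.data < 0):
            raise ValueError(f"atlas {name!r} has negative values")
        m = vol.data >= threshold
        if not m.any():
            warnings.warn(f"ROI {name!r}: empty mask at threshold {threshold}")
        masks[name] = m
    if affine is None:
        raise ValueError("atlas has no ROIs")
    return RoiSet(masks=masks, affine=affine, provenance={"threshold": threshold})


def make_sphere_mask(
    center_world: tuple[float, float, float],
    volume_mm3: float,
    grid: ImageVolume,
) -> np.ndarray:
    """Boolean sphere mask of a given VOLUME (mm^3) around a world-mm center.

    The radius is r = (3 V / 4 pi)^(1/3); a voxel is included iff its
    world-coordinate center lies within r of ``center_world``.
    """
    if volume_mm3 <= 0:
        raise ValueError("sphere volume must be positive")
    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    shape = grid.spatial_shape
    idx = np.indices(shape).reshape(3, -1).T
    xyz = grid.world_coords(idx)
    d2 = ((xyz - np.asarray(center_world, dtype=float)) ** 2).sum(axis=1)
    mask = (d2 <= r * r).reshape(shape)
    if not mask.any():
        # guarantee at least the nearest voxel center (smallest spheres)
        nearest = np.argmin(d2)
        # but only if the center itself is inside the grid bounds
        lo = grid.world_coords(np.zeros((1, 3)))[0]
        hi = grid.world_coords(np.array([[s - 1 for s in shape]], dtype=float))[0]
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        c = np.asarray(center_world, dtype=float)
        if np.any(c < lo - 0.5) or np.any(c > hi + 0.5):
            raise ValueError("sphere center lies outside the grid")
        mask.flat[nearest] = True
    return mask


def build_gm_mask(
    mean_gm: ImageVolume,
    mean_wm: ImageVolume,
    floor: float = 0.20,
) -> np.ndarray:
    """Explicit gray-matter mask: mean GM probability strictly above both the
    mean WM probability and a floor (default 0.20)."""
    if mean_gm.data.shape != mean_wm.data.shape:
        raise ValueError("GM and WM maps must share one grid")
    gm = mean_gm.data
    wm = mean_wm.data
    return (gm > wm) & (gm > floor)


def flip_lateralized(volume: ImageVolume, most_affected_side: str) -> ImageVolume:
    """Mirror a volume about the mid-sagittal plane when the clinically most
    affected side is the right, so the affected hemisphere of every analyzed
    map lies on the left.

    ``most_affected_side`` in {"left", "right", "none"}; "left" and "none"
    are identities. The grid is assumed symmetric about its mid-sagittal
    plane (the phantom's is by construction), so the mirror is an index
    reversal along the left-right (first) axis.
    """
    if most_affected_side not in ("left", "right", "none"):
        raise ValueError(f"unknown side {most_affected_side!r}")
    if most_affected_side in ("left", "none"):
        return volume
    return ImageVolume(data=volume.data[::-1].copy(), affine=volume.affine.copy())


def gaussian_smooth(
    volume: ImageVolume,
    fwhm_mm: float,
    mask: np.ndarray | None = None,
) -> ImageVolume:
    """Isotropic Gaussian smoothing with a kernel specified by FWHM in mm.

    sigma per axis is fwhm / sqrt(8 ln 2) divided by the voxel size along
    that axis. With ``mask`` given, performs mask-weighted smoothing
    (smooth(v*m)/smooth(m)) inside the mask and leaves outside voxels
    untouched — the stand-in for tissue-weighted smoothing.

    Boundary handling replicates the nearest edge value, which conserves
    constants on small grids.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return ImageVolume(data=volume.data.copy(), affine=volume.affine.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / volume.voxel_sizes

    def _smooth3(arr: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(arr.astype(float), sigma=sigma_vox, mode="nearest")

    data = volume.data
    if data.ndim == 4:
        out = np.stack(
            [_smooth_one(data[..., k], sigma_vox, mask, _smooth3) for k in range(data.shape[-1])],
            axis=-1,
        )
    else:
        out = _smooth_one(data, sigma_vox, mask, _smooth3)
    return ImageVolume(data=out, affine=volume.affine.copy())


def _smooth_one(arr, sigma_vox, mask, smoother):
    if mask is None:
        return smoother(arr)
    m = mask.astype(float)
    num = smoother(np.where(mask, arr, 0.0))  # zero-fill so NaN outside stays outside
    den = smoother(m)
    out = arr.astype(float).copy()
    inside = mask.astype(bool) & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out
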