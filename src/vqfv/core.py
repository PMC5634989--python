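"""Core image containers and voxel-lattice bookkeeping.

Volumes and masks live on a shared axis-aligned lattice described by a
per-axis voxel spacing (mm) and the physical position of voxel (0, 0, 0)
(mm).  Axis convention throughout the package: axis 0 = left-right,
axis 1 = anterior-posterior (anterior at index 0), axis 2 =
inferior-superior (superior at the last index).

Masks are defined on the voxel lattice: a voxel is wholly in or out, and
physical volume is ``voxel_count * voxel_volume_ml``.  Sub-voxel surface
precision is deliberately out of scope because every downstream quantity
is a volume ratio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
from scipy import ndimage

#: agreement tolerance (mm) for spacing/origin when two grids are compared
LATTICE_TOL_MM = 1e-3


class Modality(str, Enum):
    """Modality tag carried by an :class:`ImageVolume`."""

    CT = "CT"
    PET_VENT = "PET_VENT"
    PET_PERF = "PET_PERF"


class LatticeMismatchError(ValueError):
    """Two grids that must share a lattice do not (resample upstream)."""


def _as_triple(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries, got {len(t)}")
    return t


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular lattice.

    Parameters
    ----------
    data:
        3-D array; Hounsfield units for CT, activity (arbitrary units,
        e.g. expected or measured counts per voxel) for PET.
    spacing:
        Per-axis voxel size in mm, all entries > 0.
    origin:
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    modality:
        One of :class:`Modality`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return math.prod(self.spacing) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-physical affine (axis-aligned)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class BinaryMask:
    """A boolean region on the same lattice as its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            self.data = self.data > 0
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @classmethod
    def like(cls, parent: "ImageVolume | BinaryMask", data: np.ndarray, label: str = "") -> "BinaryMask":
        """Mask on the same lattice as ``parent``."""
        if data.shape != parent.data.shape:
            raise ValueError(f"mask shape {data.shape} != parent shape {parent.data.shape}")
        return cls(data=data, spacing=parent.spacing, origin=parent.origin, label=label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return math.prod(self.spacing) / 1000.0

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml


@dataclass
class CaseRecord:
    """One subject: CT, optional ventilation/perfusion PET, optional PFTs.

    ``pft`` maps index name (``FEV1_FVC``, ``FEV1_pct_pred``,
    ``DLCO_pct_pred``, ``FVC_pct_pred``) to a finite positive value
    (fraction for FEV1/FVC, percent-of-predicted otherwise).
    """

    case_id: str
    ct: ImageVolume
    pet_vent: Optional[ImageVolume] = None
    pet_perf: Optional[ImageVolume] = None
    pft: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for vol in (self.pet_vent, self.pet_perf):
            if vol is not None:
                assert_same_lattice(self.ct, vol)
        if self.pft is not None:
            for k, v in self.pft.items():
                if not (np.isfinite(v) and v > 0):
                    raise ValueError(f"PFT value {k}={v!r} must be finite and > 0")


PFT_INDICES = ("FEV1_FVC", "FEV1_pct_pred", "DLCO_pct_pred", "FVC_pct_pred")


def same_lattice(a, b, tol: float = LATTICE_TOL_MM) -> bool:
    """True when two volumes/masks share shape, spacing and origin."""
    return (
        a.data.shape == b.data.shape
        and all(abs(x - y) <= tol for x, y in zip(a.spacing, b.spacing))
        and all(abs(x - y) <= tol for x, y in zip(a.origin, b.origin))
    )


def assert_same_lattice(a, b, tol: float = LATTICE_TOL_MM) -> None:
    """Raise :class:`LatticeMismatchError` unless ``a`` and ``b`` share a lattice.

    Shapes must be equal and spacing/origin must agree within ``tol`` mm.
    A failure signals that the caller must resample upstream (see
    :func:`resample_to`); nothing in the package resamples silently.
    """
    if a.data.shape != b.data.shape:
        raise LatticeMismatchError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not all(abs(x - y) <= tol for x, y in zip(a.spacing, b.spacing)):
        raise LatticeMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not all(abs(x - y) <= tol for x, y in zip(a.origin, b.origin)):
        raise LatticeMismatchError(f"origin mismatch: {a.origin} vs {b.origin}")


def resample_to(vol: "ImageVolume | BinaryMask", reference: "ImageVolume | BinaryMask",
                order: Optional[int] = None) -> "ImageVolume | BinaryMask":
    """Resample ``vol`` onto the lattice of ``reference``.

    Interpolation is trilinear for image volumes (``order=1``) and
    nearest-neighbour for masks (``order=0``) unless overridden.  Both
    lattices must be axis-aligned (the only geometry this package
    produces or accepts).  Voxels mapped from outside the source grid
    get the source minimum (volumes) or False (masks).
    """
    is_mask = isinstance(vol, BinaryMask)
    if order is None:
        order = 0 if is_mask else 1
    # physical coords of reference voxel centres -> fractional source indices
    coords = [
        (reference.origin[ax] + np.arange(reference.data.shape[ax]) * reference.spacing[ax]
         - vol.origin[ax]) / vol.spacing[ax]
        for ax in range(3)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    src = vol.data.astype(float)
    fill = 0.0 if is_mask else float(np.min(src))
    out = ndimage.map_coordinates(src, np.stack(grid), order=order, mode="constant", cval=fill)
    if is_mask:
        return BinaryMask(out > 0.5, reference.spacing, reference.origin, label=vol.label)
    return ImageVolume(out, reference.spacing, reference.origin, modality=vol.modality)


def sphere_mask(shape: tuple[int, int, int], spacing: tuple[float, float, float],
                center_vox, radius_mm: float) -> np.ndarray:
    """Boolean rasterisation of a sphere given in voxel-centre coordinates.

    A voxel is inside iff its centre lies within ``radius_mm`` of the
    sphere centre (itself given in voxel units, possibly fractional).
    Uses a bounding box so large grids stay cheap.
    """
    out = np.zeros(shape, dtype=bool)
    lo, hi, axes = [], [], []
    for ax in range(3):
        r_vox = radius_mm / spacing[ax]
        a = max(0, int(math.floor(center_vox[ax] - r_vox)))
        b = min(shape[ax], int(math.ceil(center_vox[ax] + r_vox)) + 1)
        if a >= b:
            return out
        lo.append(a)
        hi.append(b)
        axes.append((np.arange(a, b) - center_vox[ax]) * spacing[ax])
    d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
          + axes[2][None, None, :] ** 2)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius_mm ** 2
    return out
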