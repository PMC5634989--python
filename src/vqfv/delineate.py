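"""Percentage-of-maximum delineation of functional lung volumes.

The core method: a functional volume at cutoff ``c`` is the set of
whole-lung voxels whose PET activity is at least ``c/100`` of a
reference maximum.  The reference maximum is the highest in-lung value
after excluding focal airway-deposition hot spots, which would otherwise
inflate the maximum and shrink every delineated volume.

Thresholds are fractional, so all masks are invariant to rescaling the
PET values; and because every cutoff shares one reference maximum, the
masks of a sweep are nested and their volumes non-increasing by
construction.  A voxel exactly at the threshold is inside (``>=``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, ImageVolume, assert_same_lattice, sphere_mask

DEFAULT_CUTOFFS: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 40, 50)

#: 26-neighbourhood for hot-spot cluster labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MaxEstimate:
    """Reference maximum with hot-spot exclusion bookkeeping."""

    value: float
    excluded_mask: BinaryMask
    policy: str  # auto | manual_value | manual_roi
    diagnostics: dict = field(default_factory=dict)


def estimate_max(pet: ImageVolume, wl: BinaryMask, policy: str = "auto",
                 manual_value: Optional[float] = None,
                 manual_roi: Optional[BinaryMask] = None,
                 peak_ratio: float = 1.5, max_hot_ml: float = 5.0,
                 exclusion_margin_mm: float = 8.0) -> MaxEstimate:
    """Estimate the reference maximum inside the whole-lung mask.

    Policies
    --------
    ``auto``
        Flag 26-connected clusters of voxels above ``peak_ratio`` times
        the in-lung 99.5th percentile whose volume is at most
        ``max_hot_ml`` (larger supra-threshold regions are taken to be
        genuine high uptake, not deposition foci).  Flagged clusters are
        dilated by ``exclusion_margin_mm`` — roughly one PSF width — so
        the blur skirt of a focus cannot stand in for it; the value is
        the maximum over the remaining lung.
    ``manual_value``
        Use ``manual_value`` as given (the operator read it off).
    ``manual_roi``
        Maximum over the lung minus an operator-drawn exclusion ROI.
    """
    assert_same_lattice(pet, wl)
    if wl.voxel_count == 0:
        raise ValueError("empty whole-lung mask")
    in_lung = pet.data[wl.data]
    raw_max = float(in_lung.max())
    empty = BinaryMask.like(wl, np.zeros(wl.shape, dtype=bool), label="hotspot-exclusion")

    if policy == "manual_value":
        if manual_value is None or manual_value <= 0:
            raise ValueError("manual_value policy requires a positive manual_value")
        return MaxEstimate(float(manual_value), empty, policy,
                           {"raw_max": raw_max, "p995": float(np.percentile(in_lung, 99.5)),
                            "n_excluded_voxels": 0})

    if policy == "manual_roi":
        if manual_roi is None:
            raise ValueError("manual_roi policy requires a manual_roi mask")
        assert_same_lattice(pet, manual_roi)
        keep = wl.data & ~manual_roi.data
        if not keep.any():
            raise ValueError("manual ROI excludes the entire lung")
        value = float(pet.data[keep].max())
        if value <= 0:
            raise ValueError("non-positive reference maximum")
        excl = BinaryMask.like(wl, manual_roi.data & wl.data, label="hotspot-exclusion")
        return MaxEstimate(value, excl, policy,
                           {"raw_max": raw_max, "p995": float(np.percentile(in_lung, 99.5)),
                            "n_excluded_voxels": excl.voxel_count})

    if policy != "auto":
        raise ValueError(f"unknown max-estimation policy {policy!r}")

    p995 = float(np.percentile(in_lung, 99.5))
    cand = wl.data & (pet.data > peak_ratio * p995)
    flagged = np.zeros(wl.shape, dtype=bool)
    if cand.any():
        labels, n = ndimage.label(cand, structure=_CONN26)
        counts = np.bincount(labels.ravel())
        max_vox = max_hot_ml / wl.voxel_volume_ml
        for i in range(1, n + 1):
            if counts[i] <= max_vox:
                flagged |= labels == i
    n_core = int(flagged.sum())
    if n_core and exclusion_margin_mm > 0:
        r = [max(1, int(round(exclusion_margin_mm / s))) for s in wl.spacing]
        grids = np.ogrid[-r[0]:r[0] + 1, -r[1]:r[1] + 1, -r[2]:r[2] + 1]
        d2 = sum((g * s) ** 2 for g, s in zip(grids, wl.spacing))
        flagged = ndimage.binary_dilation(flagged, structure=d2 <= exclusion_margin_mm**2)
    keep = wl.data & ~flagged
    if not keep.any():
        raise ValueError("hot-spot exclusion removed the entire lung")
    value = float(pet.data[keep].max())
    if value <= 0:
        raise ValueError("non-positive reference maximum")
    excl = BinaryMask.like(wl, flagged & wl.data, label="hotspot-exclusion")
    return MaxEstimate(value, excl, "auto",
                       {"raw_max": raw_max, "p995": p995, "n_excluded_voxels": n_core})


def delineate_at(pet: ImageVolume, wl: BinaryMask, max_est: MaxEstimate,
                 cutoff_pct: float) -> tuple[BinaryMask, float]:
    """Functional mask and %WL volume at one cutoff.

    ``mask = {voxel in WL : activity >= cutoff/100 * max}``;
    ``volume_pct_wl = 100 * |mask| / |WL|``.
    """
    assert_same_lattice(pet, wl)
    if not (0.0 < cutoff_pct < 100.0):
        raise ValueError(f"cutoff_pct must be in (0, 100), got {cutoff_pct}")
    n_wl = wl.voxel_count
    if n_wl == 0:
        raise ValueError("empty whole-lung mask")
    thr = (cutoff_pct / 100.0) * max_est.value
    mask = BinaryMask.like(wl, wl.data & (pet.data >= thr), label="functional")
    return mask, 100.0 * mask.voxel_count / n_wl


@dataclass
class ThresholdSweep:
    """Per-cutoff delineation results for one PET volume."""

    cutoffs_pct: tuple[float, ...]
    masks: list[BinaryMask]
    abs_thresholds: list[float]
    volumes_pct_wl: list[float]
    max_estimate: MaxEstimate

    def mask_at(self, cutoff_pct: float) -> BinaryMask:
        return self.masks[self.cutoffs_pct.index(cutoff_pct)]

    def volume_at(self, cutoff_pct: float) -> float:
        return self.volumes_pct_wl[self.cutoffs_pct.index(cutoff_pct)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff_pct": self.cutoffs_pct,
            "abs_threshold": self.abs_thresholds,
            "voxels": [m.voxel_count for m in self.masks],
            "volume_pct_wl": self.volumes_pct_wl,
        })


def sweep(pet: ImageVolume, wl: BinaryMask, max_est: MaxEstimate,
          cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> ThresholdSweep:
    """Delineate at every cutoff of a strictly increasing list."""
    cutoffs = tuple(float(c) for c in cutoffs)
    if not cutoffs or any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"cutoffs must be strictly increasing, got {cutoffs}")
    masks, thrs, vols = [], [], []
    for c in cutoffs:
        m, v = delineate_at(pet, wl, max_est, c)
        masks.append(m)
        thrs.append((c / 100.0) * max_est.value)
        vols.append(v)
    return ThresholdSweep(cutoffs, masks, thrs, vols, max_est)
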