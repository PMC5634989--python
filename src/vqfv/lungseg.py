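"""Whole-lung (WL) delineation from CT by Hounsfield-unit thresholding.

Aerated lung sits well below soft tissue on the HU scale, so a single
cutoff (default -400 HU) followed by morphological cleanup recovers the
lungs: outside-body air is removed as the border-connected low-HU
component, small air pockets are dropped by a minimum component volume,
the up-to-two largest components are kept (left/right lungs may merge at
the mediastinum), then closing and hole filling smooth the contour.
Trachea/main bronchi are optionally removed by a region grow seeded on
the top slice at a stricter cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, Modality, sphere_mask


@dataclass
class LungSegParams:
    """Tunable parameters of :func:`segment_lungs`.

    ``hu_threshold`` must lie strictly between air (-1000) and water (0);
    ``min_component_ml`` rejects sub-lung-sized air pockets.
    """

    hu_threshold: float = -400.0
    min_component_ml: float = 100.0
    closing_radius_mm: float = 6.0
    fill_holes: bool = True
    exclude_airways: bool = True
    airway_hu: float = -950.0

    def __post_init__(self) -> None:
        if not (-1000.0 < self.hu_threshold < 0.0):
            raise ValueError(f"hu_threshold must be in (-1000, 0), got {self.hu_threshold}")
        if self.min_component_ml <= 0:
            raise ValueError("min_component_ml must be > 0")


class SegmentationError(RuntimeError):
    """No lung-sized component found (non-thoracic or corrupt CT)."""


def _closing_footprint(radius_mm: float, spacing) -> np.ndarray:
    r = [max(0, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.ogrid[-r[0] : r[0] + 1, -r[1] : r[1] + 1, -r[2] : r[2] + 1]
    d2 = sum(((g * s) ** 2 for g, s in zip(grids, spacing)))
    return d2 <= radius_mm**2


def segment_lungs(ct: ImageVolume, params: LungSegParams | None = None) -> BinaryMask:
    """Delineate the whole-lung volume on CT.

    Returns a mask labelled ``WL``.  Raises :class:`SegmentationError`
    when no retained component reaches ``min_component_ml``.
    """
    if ct.modality != Modality.CT:
        raise ValueError(f"segment_lungs expects a CT volume, got {ct.modality}")
    params = params or LungSegParams()
    air = ct.data < params.hu_threshold

    # drop outside-body air: any low-HU component touching the volume border
    labels, n = ndimage.label(air)
    border_ids = set()
    for ax in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[ax] = sl
            border_ids |= set(np.unique(labels[tuple(idx)]))
    border_ids.discard(0)
    inside = air & ~np.isin(labels, sorted(border_ids))

    # keep up to two largest components of at least min_component_ml
    labels, n = ndimage.label(inside)
    if n == 0:
        raise SegmentationError("no lung-sized component below the HU threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    min_vox = params.min_component_ml / ct.voxel_volume_ml
    big = [i for i in np.argsort(counts)[::-1][:2] if counts[i] >= min_vox]
    if not big:
        raise SegmentationError(
            f"no lung-sized component >= {params.min_component_ml} ml "
            f"(largest: {counts.max() * ct.voxel_volume_ml:.1f} ml)")
    mask = np.isin(labels, big)

    if params.closing_radius_mm > 0:
        mask = ndimage.binary_closing(
            mask, structure=_closing_footprint(params.closing_radius_mm, ct.spacing))
        # closing may only add within the original support + dilation; keep monotone
        mask |= np.isin(labels, big)
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)

    if params.exclude_airways:
        strict = ct.data < params.airway_hu
        tl, _ = ndimage.label(strict)
        top_ids = set(np.unique(tl[:, :, -1]))  # superior = last slice, axis 2
        top_ids.discard(0)
        if top_ids:
            mask &= ~np.isin(tl, sorted(top_ids))

    return BinaryMask(mask, ct.spacing, ct.origin, label="WL")


def manual_adjust(mask: BinaryMask, edits: Iterable[tuple[str, tuple, float]]) -> BinaryMask:
    """Apply scripted spherical add/remove edits, in order.

    ``edits`` is an iterable of ``(op, center_vox, radius_mm)`` with
    ``op`` in ``{"add", "remove"}``.  This is the scripted, auditable
    counterpart of an expert's on-screen contour adjustment.  Raises if
    an edit sphere covers no voxel of the grid.
    """
    out = mask.data.copy()
    for op, center, radius_mm in edits:
        sph = sphere_mask(mask.shape, mask.spacing, center, radius_mm)
        if not sph.any():
            raise ValueError(f"edit sphere at {center} r={radius_mm}mm lies entirely outside the grid")
        if op == "add":
            out |= sph
        elif op == "remove":
            out &= ~sph
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return BinaryMask(out, mask.spacing, mask.origin, label=mask.label)
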