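"""Volume, mask, tabular and configuration I/O.

NIfTI-1 is the canonical interchange format (single bit-exact test
surface); DICOM series are import-only.  Non-finite voxels encountered
at load time are repaired to the finite minimum of the volume and
logged — downstream thresholding assumes finite data.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml

from .core import BinaryMask, ImageVolume, Modality, PFT_INDICES

logger = logging.getLogger("vqfv")


def get_logger(name: str = "vqfv") -> logging.Logger:
    """Package logger; emits ``stage | case | message`` style lines."""
    lg = logging.getLogger(name)
    if not lg.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        lg.addHandler(h)
        lg.setLevel(logging.INFO)
    return lg


def _repair_nonfinite(data: np.ndarray, where: str) -> np.ndarray:
    bad = ~np.isfinite(data)
    if bad.any():
        finite = data[~bad]
        fill = float(finite.min()) if finite.size else 0.0
        data = np.where(bad, fill, data)
        logger.warning("io | %s | repaired %d non-finite voxels to %g", where, int(bad.sum()), fill)
    return data


def read_volume(path, modality: Modality | str) -> ImageVolume:
    """Read a NIfTI-1 file or a single-series DICOM directory.

    CT DICOM values are rescaled to HU with the header slope/intercept;
    slices are sorted by position along the slice normal.  Raises on a
    missing path, a mixed-series directory, or slice spacing that is
    non-uniform beyond 1%.
    """
    path = Path(path)
    modality = Modality(modality)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path, modality)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    data = _repair_nonfinite(data, str(path))
    zooms = [float(z) for z in img.header.get_zooms()[:3]]
    origin = [float(x) for x in img.affine[:3, 3]]
    return ImageVolume(data, tuple(zooms), tuple(origin), modality)


def read_mask(path, label: str = "") -> BinaryMask:
    """Read a NIfTI label image as a boolean mask (non-zero = inside)."""
    vol = read_volume(path, Modality.CT)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin, label=label)


def write_volume(vol: ImageVolume | BinaryMask, path) -> None:
    """Write as NIfTI-1; masks become uint8 {0, 1}, volumes float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    aff = np.diag([*vol.spacing, 1.0])
    aff[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(data, aff), str(path))


def _read_dicom_series(dirpath: Path, modality: Modality) -> ImageVolume:
    files = sorted(p for p in dirpath.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"empty DICOM directory: {dirpath}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    uids = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(uids) != 1:
        raise ValueError(f"mixed-series DICOM directory ({len(uids)} series): {dirpath}")
    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[:3], iop[3:])
    order = sorted(range(len(slices)),
                   key=lambda i: float(np.dot(normal, np.asarray(slices[i].ImagePositionPatient, dtype=float))))
    slices = [slices[i] for i in order]
    pos = np.array([float(np.dot(normal, np.asarray(s.ImagePositionPatient, dtype=float))) for s in slices])
    if len(slices) > 1:
        dz = np.diff(pos)
        if dz.min() <= 0 or (dz.max() - dz.min()) > 0.01 * abs(dz.mean()):
            raise ValueError(f"non-uniform DICOM slice spacing beyond 1%: {dirpath}")
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    planes = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        # pixel_array is (row, col); package axes are (x=col, y=row, z=slice)
        planes.append(s.pixel_array.astype(float).T * slope + intercept)
    data = _repair_nonfinite(np.stack(planes, axis=-1), str(dirpath))
    ps = [float(v) for v in slices[0].PixelSpacing]  # (row, col) spacing
    spacing = (ps[1], ps[0], slice_spacing)
    origin = tuple(float(x) for x in slices[0].ImagePositionPatient)
    return ImageVolume(data, spacing, origin, modality)


def read_pft_table(path) -> pd.DataFrame:
    """Read a PFT CSV (columns: case_id + the four indices), indexed by case."""
    df = pd.read_csv(path)
    missing = [c for c in ("case_id", *PFT_INDICES) if c not in df.columns]
    if missing:
        raise ValueError(f"PFT table missing columns: {missing}")
    return df.set_index("case_id")


def write_pft_table(rows: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index_label="case_id")


def load_config(path) -> dict:
    """Load a YAML (or flat key: value) configuration file as a dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}
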