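"""NIfTI and table I/O helpers.

Exams are stored as 4-D NIfTI volumes (last axis = phase), masks as 3-D
binary NIfTI volumes, feature tables and clinical tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DCESeries, TumorMask


def save_series(series: DCESeries, path) -> None:
    """Write an exam as a 4-D NIfTI file (x, y, z, phase)."""
    data = np.moveaxis(series.phases, 0, -1)
    affine = np.diag(list(series.spacing) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header["descrip"] = series.exam_timing.encode()
    nib.save(img, str(path))


def load_series(path, exam_timing: str | None = None) -> DCESeries:
    """Read a 4-D NIfTI exam; timing falls back to the header description."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 4:
        raise ValueError(f"{path}: expected a 4-phase 4-D volume, got {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if exam_timing is None:
        desc = bytes(img.header["descrip"]).split(b"\x00")[0].decode() or "bef"
        exam_timing = desc
    return DCESeries(np.moveaxis(data, -1, 0), spacing=spacing, exam_timing=exam_timing)


def save_mask(mask: TumorMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


def load_mask(path, provenance: str = "corrected") -> TumorMask:
    img = nib.load(str(path))
    return TumorMask(np.asarray(img.dataobj) > 0, provenance=provenance)


def save_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def load_table(path, index_col: str = "lesion_id") -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)
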