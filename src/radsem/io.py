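"""Reading and writing volumes, masks, semantic score tables, feature tables.

Volumes and masks are NIfTI-1 (``.nii``/``.nii.gz``) or NRRD, handled by
SimpleITK; intensities pass through unmodified and spacing comes from the
header.  SimpleITK arrays arrive as (z, y, x); we transpose to this package's
(x, y, z) convention on read and back on write.

CSV dialect: UTF-8, comma separator, ``.`` decimal, mandatory header row.
Undefined feature values (NaN) serialize as empty cells and are reported via
the module logger.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .semantic import CohortTable, validate_cohort_frame
from .volume import RegionMask, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_semantic_scores",
    "write_semantic_scores",
    "read_feature_table",
    "write_feature_table",
]

logger = logging.getLogger(__name__)

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_path(path: os.PathLike | str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    name = p.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(f"unsupported image format for {p}; expected NIfTI or NRRD")
    return p


def read_volume(path: os.PathLike | str) -> VoxelVolume:
    """Read a 3D NIfTI/NRRD image into a :class:`VoxelVolume`."""
    p = _check_path(path)
    try:
        img = sitk.ReadImage(str(p))
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise IOError(f"unreadable image header in {p}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{p}: expected 3 dimensions, got {img.GetDimension()}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return VoxelVolume(
        intensities=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(volume: VoxelVolume, path: os.PathLike | str) -> None:
    """Write a :class:`VoxelVolume` as NIfTI/NRRD (format from the suffix)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: os.PathLike | str, companion: VoxelVolume) -> RegionMask:
    """Read a binary mask and verify alignment with its companion volume.

    Any nonzero voxel is foreground (0/1 and 0/255 dialects both work).
    """
    vol = read_volume(path)
    mask = RegionMask(vol.intensities, vol.spacing, vol.origin)
    mask.check_companion(companion)
    if mask.n_foreground == 0:
        raise ValueError(f"empty mask in {path}")
    return mask


def write_mask(mask: RegionMask, path: os.PathLike | str) -> None:
    write_volume(VoxelVolume(mask.voxels.astype(np.uint8), mask.spacing, mask.origin), path)


def read_semantic_scores(path: os.PathLike | str) -> CohortTable:
    """Read and validate a semantic score CSV (subject_id + 9 score columns)."""
    frame = pd.read_csv(path)
    return validate_cohort_frame(frame)


def write_semantic_scores(cohort: CohortTable, path: os.PathLike | str) -> None:
    cohort.frame.to_csv(path, index=True)


def write_feature_table(table: pd.DataFrame, path: os.PathLike | str) -> None:
    """Write a subjects x features table as CSV.

    Columns are named ``<filter>.<family>.<feature>`` (filter one of
    ``orig``, ``log.sigma<s>``, ``wv.<subband>``) and written in the table's
    column order, which the extractor fixes deterministically.  NaN values
    (declared-undefined features) become empty cells.
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    n_nan = int(table.isna().to_numpy().sum())
    if n_nan:
        logger.warning("feature table contains %d undefined (NaN) values; "
                       "serialized as empty cells", n_nan)
    table.to_csv(path, index=True, index_label="subject_id", na_rep="")


def read_feature_table(path: os.PathLike | str) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    return df.astype(float)
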