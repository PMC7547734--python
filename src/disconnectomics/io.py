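"""Readers and writers for the pipeline's on-disk formats.

Volumes are NIfTI, streamlines TRK/TCK (kept in world mm), tables TSV, and
every written volume can carry a JSON sidecar echoing the parameters that
produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.trk import Field as _TrkField

from .datatypes import Tractogram
from .grids import check_affine, voxel_sizes

__all__ = [
    "read_volume",
    "write_volume",
    "read_tractogram",
    "write_tractogram",
    "read_table",
    "write_table",
    "write_sidecar",
]


def read_volume(path):
    """Load a 3-D NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}-D; a 3-D volume is required")
    affine = check_affine(img.affine)
    return data, affine


def write_volume(volume, affine, path, dtype=None, sidecar: dict | None = None):
    volume = np.asarray(volume)
    if dtype is None:
        dtype = np.int16 if volume.dtype in (bool, np.int32, np.int16) else np.float32
    img = nib.Nifti1Image(volume.astype(dtype), check_affine(affine))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    if sidecar is not None:
        write_sidecar(path, sidecar)
    return path


def write_sidecar(volume_path, params: dict):
    p = Path(volume_path)
    side = p.with_suffix("").with_suffix(".json") if p.suffix == ".gz" else p.with_suffix(".json")
    side.write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
    return side


def read_tractogram(path, subject_id: str | None = None) -> Tractogram:
    """Load a TRK/TCK file; streamlines come back in world (mm) coordinates."""
    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise ValueError(f"unknown tractogram extension {path.suffix!r}")
    f = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in f.streamlines]
    affine = f.header.get(_TrkField.VOXEL_TO_RASMM)
    shape = f.header.get(_TrkField.DIMENSIONS)
    return Tractogram(
        subject_id=subject_id or path.stem,
        streamlines=streamlines,
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        shape=None if shape is None else tuple(int(d) for d in shape),
    )


def write_tractogram(tractogram: Tractogram, path, shape=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib_t = _NibTractogram(tractogram.streamlines, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        shape = shape or tractogram.shape
        if shape is None:
            raise ValueError("TRK output needs a reference grid shape")
        header = {
            _TrkField.VOXEL_TO_RASMM: np.asarray(tractogram.affine, dtype=np.float32),
            _TrkField.VOXEL_SIZES: tuple(voxel_sizes(tractogram.affine)),
            _TrkField.DIMENSIONS: tuple(int(d) for d in shape),
        }
        nib.streamlines.save(nib_t, str(path), header=header)
    elif path.suffix.lower() == ".tck":
        nib.streamlines.save(nib_t, str(path))
    else:
        raise ValueError(f"unknown tractogram extension {path.suffix!r}")
    return path


def write_table(df: pd.DataFrame, path, index: bool = True):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
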