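"""Readers and writers for the package's on-disk formats.

Pattern datasets travel as flat CSV (label columns followed by one column per
voxel), masks and statistic maps as NIfTI with the voxel size encoded in the
affine, RDMs as labeled CSV matrices, and configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datasets import LABEL_COLUMNS, PatternDataset, VolumeMask
from .geometry import RDM

_FLOAT_FMT = "%.12g"


def dataset_to_csv(ds: PatternDataset, path: str | Path) -> None:
    """Write labels plus voxel columns (v000000, ...) as one CSV."""
    vox = pd.DataFrame(
        ds.patterns,
        columns=[f"v{j:06d}" for j in range(ds.n_voxels)],
    )
    pd.concat([ds.labels.reset_index(drop=True), vox], axis=1).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def dataset_from_csv(path: str | Path) -> PatternDataset:
    df = pd.read_csv(path)
    vox_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    return PatternDataset(
        df[vox_cols].to_numpy(dtype=float), df[list(LABEL_COLUMNS)].copy()
    )


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_mask(mask: VolumeMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(mask.voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> VolumeMask:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return VolumeMask(np.asarray(img.dataobj) > 0, tuple(float(z) for z in zooms))


def save_map(data: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    """Write a 3-D statistic map (NaN outside the mask) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def rdm_to_csv(rdm: RDM, path: str | Path) -> None:
    names = [f"o{o}t{t}_{p[:4]}" for o, t, p in rdm.conditions]
    pd.DataFrame(rdm.distances, index=names, columns=names).to_csv(
        path, float_format=_FLOAT_FMT
    )


def rdm_from_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
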