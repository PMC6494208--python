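"""Light I/O helpers: NIfTI volumes/masks and TSV tables."""

from __future__ import annotations

import numpy as np
import nibabel as nib
import pandas as pd


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 2.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_mask(mask: np.ndarray, path, voxel_size_mm: float = 2.0) -> None:
    save_nifti(np.asarray(mask, dtype=np.uint8), path, voxel_size_mm)


def load_mask(path) -> np.ndarray:
    return load_nifti(path) > 0.5


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
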