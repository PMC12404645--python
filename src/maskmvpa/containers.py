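"""On-disk containers: HDF5 for arrays, TSV for RDMs/tables, NIfTI for volumes.

HDF5 layout for epoch data::

    /data            trials x channels x times   float64
    /labels/object   trials                      int
    /labels/mask     trials                      utf-8 strings
    /time_ms         times                       float64
    /channels        channels                    utf-8 strings

TFR containers add ``/tfr/coeffs`` (complex) and ``/tfr/freqs_hz`` under
the same label groups.  RDMs travel as square TSV with a header row of
condition ids.  Every loader raises a descriptive error naming the first
missing group.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .tfr import TFRSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_tfr",
    "load_tfr",
    "save_rdm_tsv",
    "load_rdm_tsv",
    "save_volume_nifti",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _utf8(labels) -> list[str]:
    return [str(x) for x in np.asarray(labels).tolist()]


def _require(handle: h5py.File, path: str):
    if path not in handle:
        raise KeyError(
            f"malformed container {handle.filename!r}: missing group {path!r}"
        )
    return handle[path]


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels/object", data=epochs.object_label.astype(int))
        f.create_dataset("labels/mask", data=_utf8(epochs.mask_label),
                         dtype=_STR)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset("channels", data=_utf8(epochs.channel_ids), dtype=_STR)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=_require(f, "data")[()],
            object_label=_require(f, "labels/object")[()],
            mask_label=_require(f, "labels/mask").asstr()[()],
            time_ms=_require(f, "time_ms")[()],
            channel_ids=_require(f, "channels").asstr()[()],
        )


def save_tfr(path: str | Path, tfr: TFRSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tfr/coeffs", data=tfr.coeffs)
        f.create_dataset("tfr/freqs_hz", data=tfr.freqs_hz)
        f.create_dataset("labels/object", data=tfr.object_label.astype(int))
        f.create_dataset("labels/mask", data=_utf8(tfr.mask_label), dtype=_STR)
        f.create_dataset("time_ms", data=tfr.time_ms)
        f.create_dataset("channels", data=_utf8(tfr.channel_ids), dtype=_STR)


def load_tfr(path: str | Path) -> TFRSet:
    with h5py.File(path, "r") as f:
        return TFRSet(
            coeffs=_require(f, "tfr/coeffs")[()],
            freqs_hz=_require(f, "tfr/freqs_hz")[()],
            time_ms=_require(f, "time_ms")[()],
            object_label=_require(f, "labels/object")[()],
            mask_label=_require(f, "labels/mask").asstr()[()],
            channel_ids=_require(f, "channels").asstr()[()],
        )


def save_rdm_tsv(path: str | Path, rdm: np.ndarray,
                 condition_ids=None) -> None:
    """Square TSV with a header row/index of condition ids."""
    rdm = np.asarray(rdm, float)
    k = rdm.shape[0]
    if condition_ids is None:
        condition_ids = [f"cond{i}" for i in range(k)]
    df = pd.DataFrame(rdm, index=condition_ids, columns=condition_ids)
    df.to_csv(path, sep="\t")


def load_rdm_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: RDM table is not square ({df.shape})")
    return df.to_numpy(float), [str(c) for c in df.columns]


def save_volume_nifti(path: str | Path, volume: np.ndarray,
                      voxel_size_mm: float = 2.0) -> None:
    """Write a 3-D map as NIfTI-1 with an isotropic diagonal affine."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float64), affine), str(path))
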