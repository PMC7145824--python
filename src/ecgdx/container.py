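"""HDF5 + CSV dataset container.

The container mirrors the layout of the openly released test set: one
HDF5 file holding a single ``N x samples x 12`` float tensor (dataset
name ``tracings``) and a CSV sidecar whose first columns are
``exam_id,1dAVb,RBBB,LBBB,SB,AF,ST,age,sex,patient_id,date``.  Records
of unequal length are stored zero-padded to the longest, with the true
per-record length and sampling rate kept in extra ``n_samples``/``fs``
sidecar columns; when those columns are absent (as in the released test
set) every tracing is taken at face value at 400 Hz.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from ecgdx.records import CLASSES, LEAD_NAMES, ECGRecord, MeasurementSet

TRACINGS_KEY = "tracings"
SIDECAR_COLUMNS = ["exam_id", *CLASSES, "age", "sex", "patient_id", "date"]

MEASUREMENT_COLUMNS = ["heart_rate", "pr_interval", "qrs_duration", "sdnn", "n_beats"]


class FormatError(ValueError):
    """Raised when a container violates the expected layout."""


def write_dataset(
    h5_path: Optional[str],
    csv_path: Optional[str],
    records: Sequence[ECGRecord],
    labels: Optional[np.ndarray] = None,
    measurements: Optional[Sequence[MeasurementSet]] = None,
    dataset_name: str = TRACINGS_KEY,
) -> None:
    """Write records (and an optional label/measurement sidecar) to disk."""
    n = len(records)
    if labels is None:
        labels = np.zeros((n, len(CLASSES)), dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (n, len(CLASSES)):
        raise FormatError(f"label matrix must be {n} x {len(CLASSES)}, got {labels.shape}")
    if h5_path is not None:
        max_len = max(r.n_samples for r in records)
        tensor = np.zeros((n, max_len, len(LEAD_NAMES)), dtype=np.float32)
        for i, r in enumerate(records):
            tensor[i, : r.n_samples] = r.signal
        with h5py.File(h5_path, "w") as f:
            f.create_dataset(dataset_name, data=tensor)
    if csv_path is not None:
        rows = []
        for i, r in enumerate(records):
            row = {
                "exam_id": r.exam_id or f"rec{i:06d}",
                **{c: int(labels[i, j]) for j, c in enumerate(CLASSES)},
                "age": r.age if r.age is not None else "",
                "sex": r.sex or "",
                "patient_id": r.patient_id or "",
                "date": r.acquisition_date or "",
                "n_samples": r.n_samples,
                "fs": r.fs,
            }
            if measurements is not None:
                row.update(
                    {k: v for k, v in measurements[i].as_dict().items()}
                )
            rows.append(row)
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_dataset(
    h5_path: str,
    csv_path: Optional[str] = None,
    dataset_name: str = TRACINGS_KEY,
    default_fs: float = 400.0,
) -> tuple[list[ECGRecord], Optional[pd.DataFrame]]:
    """Read a container; returns records in stored order plus the sidecar.

    Raises :class:`FormatError` when the tensor is not ``N x samples x 12``
    or the sidecar row count disagrees with the tensor.
    """
    if not os.path.exists(h5_path):
        raise FileNotFoundError(h5_path)
    with h5py.File(h5_path, "r") as f:
        if dataset_name not in f:
            # Fall back to the first dataset in the file.
            keys = list(f.keys())
            if not keys:
                raise FormatError(f"{h5_path} contains no datasets")
            dataset_name = keys[0]
        tensor = np.asarray(f[dataset_name], dtype=np.float32)
    if tensor.ndim != 3 or tensor.shape[2] != len(LEAD_NAMES):
        raise FormatError(
            f"expected tensor N x samples x {len(LEAD_NAMES)}, got shape {tensor.shape}"
        )
    sidecar = None
    if csv_path is not None:
        sidecar = pd.read_csv(csv_path)
        if len(sidecar) != tensor.shape[0]:
            raise FormatError(
                f"sidecar has {len(sidecar)} rows but tensor has {tensor.shape[0]} tracings"
            )
    records: list[ECGRecord] = []
    for i in range(tensor.shape[0]):
        fs = default_fs
        n_samples = tensor.shape[1]
        exam_id = f"rec{i:06d}"
        patient_id, age, sex, date = "", None, None, None
        if sidecar is not None:
            row = sidecar.iloc[i]
            exam_id = str(row.get("exam_id", exam_id))
            if "fs" in sidecar.columns and np.isfinite(row["fs"]):
                fs = float(row["fs"])
            if "n_samples" in sidecar.columns and np.isfinite(row["n_samples"]):
                n_samples = int(row["n_samples"])
            patient_id = str(row.get("patient_id", "") or "")
            age = float(row["age"]) if "age" in sidecar.columns and str(row["age"]) not in ("", "nan") else None
            sex = str(row["sex"]) if "sex" in sidecar.columns and str(row["sex"]) not in ("", "nan") else None
            date = str(row["date"]) if "date" in sidecar.columns and str(row["date"]) not in ("", "nan") else None
        records.append(
            ECGRecord(
                signal=tensor[i, :n_samples],
                fs=fs,
                exam_id=exam_id,
                patient_id=patient_id,
                age=age,
                sex=sex,
                acquisition_date=date,
            )
        )
    return records, sidecar


def labels_from_sidecar(sidecar: pd.DataFrame) -> np.ndarray:
    """Extract the n x 6 boolean label matrix from a sidecar frame."""
    missing = [c for c in CLASSES if c not in sidecar.columns]
    if missing:
        raise FormatError(f"sidecar lacks label columns {missing}")
    return sidecar[list(CLASSES)].to_numpy().astype(bool)
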