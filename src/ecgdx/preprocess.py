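"""Signal preprocessing and dataset splitting.

The model-input contract is fixed: every tracing is resampled to 400 Hz
and zero-padded to 4096 samples per lead, independent of the recorder's
native rate (300-600 Hz) and duration (7-10 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from ecgdx.records import ECGRecord

TARGET_FS = 400.0
TARGET_LEN = 4096


def resample_record(rec: ECGRecord, target_fs: float = TARGET_FS) -> ECGRecord:
    """Band-limited resampling of each lead to ``target_fs``.

    Uses polyphase filtering with the rational rate ratio.  A record
    already at the target rate is returned unchanged (same object).
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal.astype(np.float64), frac.numerator, frac.denominator, axis=0)
    target_len = int(round(rec.n_samples * target_fs / rec.fs))
    # resample_poly yields ceil(n*up/down); trim or pad by at most one sample.
    if out.shape[0] > target_len:
        out = out[:target_len]
    elif out.shape[0] < target_len:
        out = np.pad(out, ((0, target_len - out.shape[0]), (0, 0)))
    return ECGRecord(
        signal=out.astype(np.float32),
        fs=target_fs,
        exam_id=rec.exam_id,
        patient_id=rec.patient_id,
        age=rec.age,
        sex=rec.sex,
        acquisition_date=rec.acquisition_date,
    )


def zero_pad_record(
    rec: ECGRecord,
    target_len: int = TARGET_LEN,
    placement: str = "end",
    long_policy: str = "error",
) -> ECGRecord:
    """Pad every lead with exact zeros to ``target_len`` samples.

    ``placement`` is ``"end"`` (default) or ``"symmetric"``.  Records
    longer than ``target_len`` are rejected by default; with
    ``long_policy="center-crop"`` the central window is kept instead.
    """
    if placement not in ("end", "symmetric"):
        raise ValueError(f"unknown placement {placement!r}")
    n = rec.n_samples
    if n == target_len:
        return rec
    if n > target_len:
        if long_policy == "center-crop":
            start = (n - target_len) // 2
            sig = rec.signal[start : start + target_len]
        else:
            raise ValueError(
                f"record has {n} samples, longer than target {target_len}"
            )
    else:
        pad = target_len - n
        if placement == "end":
            before, after = 0, pad
        else:
            before = pad // 2
            after = pad - before
        sig = np.pad(rec.signal, ((before, after), (0, 0)))
    return ECGRecord(
        signal=sig,
        fs=rec.fs,
        exam_id=rec.exam_id,
        patient_id=rec.patient_id,
        age=rec.age,
        sex=rec.sex,
        acquisition_date=rec.acquisition_date,
    )


def preprocess_record(
    rec: ECGRecord,
    target_fs: float = TARGET_FS,
    target_len: int = TARGET_LEN,
    placement: str = "end",
    long_policy: str = "error",
) -> ECGRecord:
    """Resample to ``target_fs`` then zero-pad to ``target_len``.

    The output shape (``target_len`` x 12) is fixed for every valid
    input; applying the pipeline twice is the identity.
    """
    return zero_pad_record(
        resample_record(rec, target_fs), target_len, placement, long_policy
    )


def preprocess_to_tensor(records: Sequence[ECGRecord], **kwargs) -> np.ndarray:
    """Stack preprocessed records into an ``N x target_len x 12`` float32
    tensor — the network's input layout."""
    return np.stack(
        [preprocess_record(r, **kwargs).signal for r in records]
    ).astype(np.float32)


@dataclass
class DatasetSplit:
    """Three-way split specification (train/validation/test fractions)."""

    strategy: str = "random"
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("random", "by_patient", "chronological"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")


def split_dataset(
    records: Sequence[ECGRecord], split: DatasetSplit
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition record indices into three disjoint, exhaustive parts.

    ``by_patient`` keeps every patient in exactly one part (parts then
    only approximate the requested fractions); ``chronological`` orders
    by acquisition date, earliest first.
    """
    n = len(records)
    f1, f2, _ = split.fractions
    c1 = int(round(f1 * n))
    c2 = int(round((f1 + f2) * n))
    if split.strategy == "random":
        order = np.random.default_rng(split.seed).permutation(n)
        return order[:c1], order[c1:c2], order[c2:]
    if split.strategy == "by_patient":
        pids = [r.patient_id for r in records]
        if any(not p for p in pids):
            raise ValueError("by_patient split requires patient_id on every record")
        uniq = sorted(set(pids))
        rng = np.random.default_rng(split.seed)
        rng.shuffle(uniq)
        by_pid: dict[str, list[int]] = {}
        for i, p in enumerate(pids):
            by_pid.setdefault(p, []).append(i)
        parts: list[list[int]] = [[], [], []]
        targets = [c1, c2 - c1, n - c2]
        k = 0
        for p in uniq:
            # Advance to the next unfilled part before assigning.
            while k < 2 and len(parts[k]) >= targets[k]:
                k += 1
            parts[k].extend(by_pid[p])
        return tuple(np.asarray(sorted(p), dtype=int) for p in parts)  # type: ignore[return-value]
    # chronological
    dates = [r.acquisition_date for r in records]
    if any(d is None or d == "" for d in dates):
        raise ValueError("chronological split requires acquisition_date on every record")
    order = np.argsort(np.asarray(dates), kind="stable")
    return order[:c1], order[c1:c2], order[c2:]
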