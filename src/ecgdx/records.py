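"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Canonical class order used everywhere (label CSV columns, score matrices,
#: network outputs): first-degree AV block, right/left bundle branch block,
#: sinus bradycardia, atrial fibrillation, sinus tachycardia.
CLASSES: tuple[str, ...] = ("1dAVb", "RBBB", "LBBB", "SB", "AF", "ST")

#: Rhythm classes are mutually exclusive in a single tracing.
RHYTHM_CLASSES: tuple[str, ...] = ("SB", "AF", "ST")

#: Standard 12-lead order used for signal matrices.
LEAD_NAMES: tuple[str, ...] = (
    "DI", "DII", "DIII", "AVR", "AVL", "AVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


def labels_to_array(labels) -> np.ndarray:
    """Coerce a label specification to a boolean vector in canonical order.

    Accepts a mapping ``{class name: bool}`` (missing classes default to
    False), a sequence of six booleans, or a sequence of class names.
    """
    out = np.zeros(len(CLASSES), dtype=bool)
    if isinstance(labels, dict):
        for name, val in labels.items():
            if name not in CLASSES:
                raise ValueError(f"unknown class {name!r}")
            out[CLASSES.index(name)] = bool(val)
        return out
    labels = list(labels)
    if not labels:
        return out
    if isinstance(labels[0], str):
        for name in labels:
            out[CLASSES.index(name)] = True
        return out
    if len(labels) != len(CLASSES):
        raise ValueError(f"expected {len(CLASSES)} labels, got {len(labels)}")
    return np.asarray(labels, dtype=bool)


@dataclass
class ECGRecord:
    """One 12-lead exam: ``signal`` is samples x 12 leads in mV."""

    signal: np.ndarray
    fs: float
    exam_id: str = ""
    patient_id: str = ""
    age: Optional[float] = None
    sex: Optional[str] = None
    acquisition_date: Optional[str] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float32)
        if self.signal.ndim != 2 or self.signal.shape[1] != len(LEAD_NAMES):
            raise ValueError(
                f"signal must be samples x {len(LEAD_NAMES)} leads, "
                f"got shape {self.signal.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class MeasurementSet:
    """Interval measurements for one exam.

    ``heart_rate`` is in bpm, ``pr_interval`` and ``qrs_duration`` in ms,
    ``sdnn`` (standard deviation of NN intervals) in ms by default — the
    same unit convention in which rule thresholds are expressed.  Missing
    values are NaN.
    """

    heart_rate: float = np.nan
    pr_interval: float = np.nan
    qrs_duration: float = np.nan
    sdnn: float = np.nan
    n_beats: int = 0

    def __post_init__(self) -> None:
        for name in ("heart_rate", "pr_interval", "qrs_duration", "sdnn"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def as_dict(self) -> dict:
        return {
            "heart_rate": float(self.heart_rate),
            "pr_interval": float(self.pr_interval),
            "qrs_duration": float(self.qrs_duration),
            "sdnn": float(self.sdnn),
            "n_beats": int(self.n_beats),
        }
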