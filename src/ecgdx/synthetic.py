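"""Seeded 12-lead ECG simulator with ground-truth labels.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on a per-lead
basis: a wave with amplitude ``a`` (mV), width ``w`` (ms, the nominal
support, read as +/- 2 standard deviations) and center ``c`` (ms relative
to the R peak) contributes ``a * W[lead] * exp(-(t-c)^2 / (2*(w/4)^2))``
to each lead, where ``W`` is a fixed 12-entry projection vector per wave.
This is the simplest morphology model that supports all six class
definitions: heart-rate classes change the RR model, first-degree AV
block stretches the P-to-QRS delay, bundle branch blocks widen the QRS
and flip the V1/V6 projection polarity, and atrial fibrillation drops
the P wave and draws irregular RR intervals.

The generator's returned measurements are ground truth (taken from the
drawn parameters and RR sequence, not re-estimated from the waveform).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ecgdx.records import CLASSES, LEAD_NAMES, RHYTHM_CLASSES, ECGRecord, MeasurementSet

WAVES = ("P", "Q", "R", "S", "T")

# Fixed per-wave 12-lead projection weights (rows: P Q R S T; columns in
# LEAD_NAMES order).  Values are nominal: a normal mean frontal axis with
# rS in V1 and qR in V6; no device statistics are published for the
# target recorders, so amplitudes are scaled to R ~ 1 mV in lead DII.
BASE_PROJECTION = np.array(
    [
        # DI    DII   DIII  AVR    AVL   AVF   V1    V2    V3    V4    V5    V6
        [0.40, 0.50, 0.25, -0.45, 0.10, 0.40, 0.20, 0.25, 0.30, 0.30, 0.30, 0.30],  # P
        [0.60, 0.80, 0.40, -0.70, 0.20, 0.60, -0.20, -0.10, 0.10, 0.30, 0.50, 0.60],  # Q
        [0.70, 1.00, 0.50, -0.85, 0.15, 0.75, 0.15, 0.35, 0.60, 0.90, 0.85, 0.75],  # R
        [0.30, 0.35, 0.20, -0.30, 0.10, 0.25, 1.00, 0.90, 0.70, 0.45, 0.30, 0.20],  # S
        [0.50, 0.70, 0.35, -0.60, 0.10, 0.50, 0.10, 0.35, 0.55, 0.70, 0.60, 0.50],  # T
    ],
    dtype=np.float64,
)

#: Default wave amplitudes in mV (P, Q, R, S, T).
DEFAULT_AMPLITUDES = np.array([0.15, -0.10, 1.00, -0.25, 0.30])

#: Generator-side cutoff for an unambiguous prolonged PR interval (ms).
#: The consensus definition (200 ms) is used, deliberately above the
#: harmonization engine's 190 ms rejection boundary so that generated
#: positives are unambiguous under the rule engine.
PR_PROLONGED_CUTOFF = 200.0

#: Generator-side cutoff for a wide QRS (ms).
QRS_WIDE_CUTOFF = 120.0


class InvalidSpecError(ValueError):
    """Raised for synthetic specifications that violate their invariants."""


@dataclass
class BeatMorphology:
    """Gaussian-bump beat template.

    ``amplitudes``/``widths``/``centers`` are length-5 arrays in wave
    order (P, Q, R, S, T); widths and centers in ms, centers relative to
    the R peak.  ``projection`` is 5 waves x 12 leads.
    """

    amplitudes: np.ndarray
    widths: np.ndarray
    centers: np.ndarray
    pr_interval: float
    qrs_duration: float
    p_present: bool = True
    projection: np.ndarray = field(default_factory=lambda: BASE_PROJECTION.copy())

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.projection = np.asarray(self.projection, dtype=float)
        for arr, name in ((self.amplitudes, "amplitudes"), (self.widths, "widths"),
                          (self.centers, "centers")):
            if arr.shape != (5,):
                raise InvalidSpecError(f"{name} must have 5 entries, got {arr.shape}")
        if np.any(self.widths <= 0):
            raise InvalidSpecError("wave widths must be positive")
        if self.p_present and not self.pr_interval > 0:
            raise InvalidSpecError("pr_interval must be positive when a P wave is present")
        if not self.qrs_duration > 0:
            raise InvalidSpecError("qrs_duration must be positive")
        if self.projection.shape != (5, len(LEAD_NAMES)):
            raise InvalidSpecError(
                f"projection must be 5 x {len(LEAD_NAMES)}, got {self.projection.shape}"
            )


def make_morphology(
    pr_interval: float = 160.0,
    qrs_duration: float = 90.0,
    p_present: bool = True,
    rbbb: bool = False,
    lbbb: bool = False,
    t_center: float = 280.0,
    amplitudes: Optional[Sequence[float]] = None,
    p_width: float = 80.0,
    t_width: float = 160.0,
) -> BeatMorphology:
    """Build a beat template from interval parameters.

    The QRS support spans ``[-d/2, d/2]`` around the R peak (``d`` =
    ``qrs_duration``): Q and S occupy the outer quarters, R the middle
    half.  The P wave is placed so that its onset (center - width/2)
    precedes the QRS onset by exactly ``pr_interval``.
    """
    d = float(qrs_duration)
    amps = DEFAULT_AMPLITUDES.copy() if amplitudes is None else np.asarray(amplitudes, float)
    wq = ws = 0.25 * d
    wr = 0.5 * d
    widths = np.array([p_width, wq, wr, ws, t_width])
    centers = np.array(
        [
            -d / 2.0 - pr_interval + p_width / 2.0,  # P onset at -(d/2 + PR)
            -(d / 2.0 - wq / 2.0),
            0.0,
            d / 2.0 - ws / 2.0,
            t_center,
        ]
    )
    proj = BASE_PROJECTION.copy()
    if rbbb and lbbb:
        raise InvalidSpecError("a beat cannot carry both RBBB and LBBB morphology")
    if rbbb:
        # Late forces point rightward: R' in V1 (positive late deflection,
        # realized by flipping the sign of the S projection there) and
        # deep slurred S in DI/V6.
        proj[3, LEAD_NAMES.index("V1")] = -1.2
        proj[3, LEAD_NAMES.index("V2")] = -0.8
        proj[3, LEAD_NAMES.index("DI")] = 1.2
        proj[3, LEAD_NAMES.index("V5")] = 1.0
        proj[3, LEAD_NAMES.index("V6")] = 1.2
    if lbbb:
        # Dominant QS in V1, broad monophasic R in DI/V6.
        proj[2, LEAD_NAMES.index("V1")] = 0.0
        proj[3, LEAD_NAMES.index("V1")] = 1.5
        proj[3, LEAD_NAMES.index("V2")] = 1.3
        proj[3, LEAD_NAMES.index("V6")] = 0.0
        proj[3, LEAD_NAMES.index("V5")] = 0.05
        proj[2, LEAD_NAMES.index("V6")] = 1.1
        proj[2, LEAD_NAMES.index("V5")] = 1.0
    return BeatMorphology(
        amplitudes=amps,
        widths=widths,
        centers=centers,
        pr_interval=pr_interval,
        qrs_duration=d,
        p_present=p_present,
        projection=proj,
    )


@dataclass
class RhythmSpec:
    """RR-interval model: regular sinus with Gaussian jitter, or the
    irregular log-normal model used for atrial fibrillation."""

    mean_hr: float = 72.0
    rr_model: str = "regular_sinus"
    rr_jitter_sd: float = 25.0  # ms, sinus model
    af_sigma: float = 0.75  # log-normal shape, irregular model
    af_rr_clip: tuple[float, float] = (0.25, 3.5)  # s

    def __post_init__(self) -> None:
        if not 20.0 < self.mean_hr < 300.0:
            raise InvalidSpecError(f"mean_hr must be in (20, 300), got {self.mean_hr}")
        if self.rr_model not in ("regular_sinus", "irregular_af"):
            raise InvalidSpecError(f"unknown rr_model {self.rr_model!r}")
        if self.rr_jitter_sd < 0:
            raise InvalidSpecError("rr_jitter_sd must be non-negative")


def af_rr_moments(rhythm: RhythmSpec, n_grid: int = 20001) -> tuple[float, float]:
    """Mean and standard deviation (s) of the clipped log-normal RR law.

    Computed by numerical integration over the clipped density; used as
    the analytic reference for the irregular RR model.
    """
    lo, hi = rhythm.af_rr_clip
    mu = np.log(60.0 / rhythm.mean_hr)
    s = rhythm.af_sigma
    # Clipping maps tail mass onto the boundaries.
    from scipy import stats

    dist = stats.lognorm(s=s, scale=np.exp(mu))
    x = np.linspace(lo, hi, n_grid)
    pdf = dist.pdf(x)
    p_lo = dist.cdf(lo)
    p_hi = dist.sf(hi)
    m1 = np.trapezoid(x * pdf, x) + lo * p_lo + hi * p_hi
    m2 = np.trapezoid(x**2 * pdf, x) + lo**2 * p_lo + hi**2 * p_hi
    return float(m1), float(np.sqrt(m2 - m1**2))


def sample_rr_sequence(
    rhythm: RhythmSpec, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ordered RR-interval sequence (s) covering ``duration`` seconds.

    The sum of returned intervals is at least ``duration``.  Reproducible
    for a fixed generator state.
    """
    if not duration > 0:
        raise InvalidSpecError(f"duration must be positive, got {duration}")
    mean_rr = 60.0 / rhythm.mean_hr
    out: list[float] = []
    total = 0.0
    while total < duration:
        if rhythm.rr_model == "regular_sinus":
            rr = mean_rr + rng.normal(0.0, rhythm.rr_jitter_sd / 1000.0)
            rr = max(rr, 0.25)
        else:
            rr = float(np.exp(rng.normal(np.log(mean_rr), rhythm.af_sigma)))
            rr = float(np.clip(rr, *rhythm.af_rr_clip))
        out.append(rr)
        total += rr
    return np.asarray(out)


@dataclass
class SyntheticRecordSpec:
    """Specification of one synthetic record.

    ``labels`` is any label form accepted by
    :func:`ecgdx.records.labels_to_array`.  At most one of the rhythm
    classes (SB, AF, ST) may be set; 1dAVb cannot combine with AF (a PR
    interval is undefined without P waves).
    """

    labels: object = field(default_factory=dict)
    duration: float = 10.0
    fs: float = 400.0
    seed: int = 0
    noise_sd: float = 0.01  # mV additive white noise
    baseline_amp: float = 0.05  # mV baseline sine wander
    baseline_freq: float = 0.33  # Hz
    pr_cutoff: float = PR_PROLONGED_CUTOFF

    def __post_init__(self) -> None:
        from ecgdx.records import labels_to_array

        self.label_vector = labels_to_array(self.labels)
        rhythm_set = [c for c in RHYTHM_CLASSES if self.label_vector[CLASSES.index(c)]]
        if len(rhythm_set) > 1:
            raise InvalidSpecError(
                f"rhythm classes are mutually exclusive, got {rhythm_set}"
            )
        if self.label_vector[CLASSES.index("1dAVb")] and self.label_vector[CLASSES.index("AF")]:
            raise InvalidSpecError("1dAVb cannot be generated together with AF (no P waves)")
        if not 7.0 <= self.duration <= 10.0:
            raise InvalidSpecError(f"duration must be in [7, 10] s, got {self.duration}")
        if not 300.0 <= self.fs <= 600.0:
            raise InvalidSpecError(f"fs must be in [300, 600] Hz, got {self.fs}")


def synthesize_beat(morph: BeatMorphology, fs: float) -> np.ndarray:
    """Render one beat as a 12 x L waveform at sampling rate ``fs``.

    The time axis spans the full wave support (2.5 standard deviations
    beyond the outermost wave on each side); the P bump is omitted when
    ``p_present`` is False.
    """
    if not fs > 0:
        raise InvalidSpecError(f"fs must be positive, got {fs}")
    sd = morph.widths / 4.0
    lo = np.min(morph.centers - 2.5 * morph.widths / 2.0) / 1000.0
    hi = np.max(morph.centers + 2.5 * morph.widths / 2.0) / 1000.0
    t = np.arange(int(np.floor(lo * fs)), int(np.ceil(hi * fs)) + 1) / fs * 1000.0  # ms
    out = np.zeros((len(LEAD_NAMES), t.size))
    for w in range(5):
        if w == 0 and not morph.p_present:
            continue
        bump = morph.amplitudes[w] * np.exp(-((t - morph.centers[w]) ** 2) / (2 * sd[w] ** 2))
        out += morph.projection[w][:, None] * bump[None, :]
    return out


def render_ecg(
    morph: BeatMorphology,
    r_times: np.ndarray,
    duration: float,
    fs: float,
    rng: Optional[np.random.Generator] = None,
    noise_sd: float = 0.0,
    baseline_amp: float = 0.0,
    baseline_freq: float = 0.33,
) -> np.ndarray:
    """Render a full record (samples x 12) from a beat template and R-peak
    times (s).  Bumps are accumulated in +/- 2.5-width windows only, so the
    cost is linear in the number of beats."""
    n = int(round(duration * fs))
    sig = np.zeros((n, len(LEAD_NAMES)))
    sd_ms = morph.widths / 4.0
    for w in range(5):
        if w == 0 and not morph.p_present:
            continue
        half = 2.5 * morph.widths[w] / 2.0 / 1000.0  # s
        c = morph.centers[w] / 1000.0
        proj = morph.amplitudes[w] * morph.projection[w]
        for r in r_times:
            i0 = max(0, int(np.floor((r + c - half) * fs)))
            i1 = min(n, int(np.ceil((r + c + half) * fs)) + 1)
            if i1 <= i0:
                continue
            tt = (np.arange(i0, i1) / fs - r) * 1000.0  # ms rel. to R
            bump = np.exp(-((tt - morph.centers[w]) ** 2) / (2 * sd_ms[w] ** 2))
            sig[i0:i1] += bump[:, None] * proj[None, :]
    if rng is not None and baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=len(LEAD_NAMES))
        tgrid = np.arange(n) / fs
        sig += baseline_amp * np.sin(2 * np.pi * baseline_freq * tgrid[:, None] + phase[None, :])
    if rng is not None and noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=sig.shape)
    return sig.astype(np.float32)


def _draw_parameters(label_vector: np.ndarray, rng: np.random.Generator, pr_cutoff: float):
    """Map class flags to (rhythm, morphology) parameters."""
    flags = {c: bool(label_vector[i]) for i, c in enumerate(CLASSES)}
    if flags["SB"]:
        mean_hr = rng.uniform(38.0, 48.0)
    elif flags["ST"]:
        mean_hr = rng.uniform(105.0, 150.0)
    elif flags["AF"]:
        mean_hr = rng.uniform(60.0, 100.0)
    elif flags["1dAVb"]:
        # Keep the (prolonged) P wave clear of the preceding T wave.
        mean_hr = rng.uniform(55.0, 80.0)
    else:
        mean_hr = rng.uniform(58.0, 95.0)
    if flags["AF"]:
        rhythm = RhythmSpec(mean_hr=mean_hr, rr_model="irregular_af")
    else:
        rhythm = RhythmSpec(mean_hr=mean_hr, rr_model="regular_sinus", rr_jitter_sd=25.0)
    pr = rng.uniform(pr_cutoff + 20.0, pr_cutoff + 100.0) if flags["1dAVb"] else rng.uniform(130.0, 180.0)
    qrs = rng.uniform(120.0, 150.0) if (flags["RBBB"] or flags["LBBB"]) else rng.uniform(70.0, 100.0)
    # QT shortens with heart rate; T position tracks sqrt(RR).
    t_center = 280.0 * np.sqrt(min(60.0 / mean_hr, 1.2))
    morph = make_morphology(
        pr_interval=pr,
        qrs_duration=qrs,
        p_present=not flags["AF"],
        rbbb=flags["RBBB"],
        lbbb=flags["LBBB"],
        t_center=t_center,
    )
    return rhythm, morph


def synthesize_record(
    spec: SyntheticRecordSpec,
) -> tuple[ECGRecord, np.ndarray, MeasurementSet]:
    """Generate one record: signal, ground-truth label vector, ground-truth
    measurements.

    The measurements come from the drawn parameters (PR/QRS from the beat
    template, heart rate and SDNN from the realized RR sequence), not from
    re-estimation on the waveform.
    """
    rng = np.random.default_rng(spec.seed)
    rhythm, morph = _draw_parameters(spec.label_vector, rng, spec.pr_cutoff)
    rr = sample_rr_sequence(rhythm, spec.duration, rng)
    t0 = rng.uniform(0.45, 0.7)
    r_times = t0 + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times < spec.duration - 0.05]
    sig = render_ecg(
        morph,
        r_times,
        spec.duration,
        spec.fs,
        rng=rng,
        noise_sd=spec.noise_sd,
        baseline_amp=spec.baseline_amp,
        baseline_freq=spec.baseline_freq,
    )
    rec = ECGRecord(signal=sig, fs=spec.fs, exam_id=f"syn{spec.seed}")
    rr_real = np.diff(r_times)
    af = spec.label_vector[CLASSES.index("AF")]
    if rr_real.size >= 1:
        hr = 60.0 / float(np.mean(rr_real))
    else:
        hr = np.nan
    sdnn = float(np.std(rr_real, ddof=1)) * 1000.0 if rr_real.size >= 2 else np.nan
    meas = MeasurementSet(
        heart_rate=hr,
        pr_interval=np.nan if af else morph.pr_interval,
        qrs_duration=morph.qrs_duration,
        sdnn=sdnn,
        n_beats=int(r_times.size),
    )
    return rec, spec.label_vector.copy(), meas


def sample_label_matrix(
    n: int, prevalences: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x 6 boolean label matrix with the requested per-class
    prevalences.

    Rhythm classes (SB, AF, ST) are drawn mutually exclusively from a
    categorical distribution, as are RBBB/LBBB; 1dAVb is drawn only on
    non-AF records at the conditional rate that preserves its requested
    marginal.  All per-class marginal prevalences therefore equal the
    request exactly in expectation.
    """
    prev = np.asarray(prevalences, dtype=float)
    if prev.shape != (len(CLASSES),):
        raise InvalidSpecError(f"need {len(CLASSES)} prevalences, got {prev.shape}")
    if np.any(prev < 0) or np.any(prev > 1):
        raise InvalidSpecError("prevalences must lie in [0, 1]")
    ridx = [CLASSES.index(c) for c in RHYTHM_CLASSES]
    if prev[ridx].sum() > 1.0:
        raise InvalidSpecError(
            f"rhythm-class prevalences sum to {prev[ridx].sum():.3f} > 1"
        )
    labels = np.zeros((n, len(CLASSES)), dtype=bool)
    # Mutually exclusive rhythm draw.
    u = rng.random(n)
    edges = np.cumsum(prev[ridx])
    for k, idx in enumerate(ridx):
        lo = 0.0 if k == 0 else edges[k - 1]
        labels[:, idx] = (u >= lo) & (u < edges[k])
    # Bundle branch blocks: mutually exclusive categorical draw.
    i1, ir, il = CLASSES.index("1dAVb"), CLASSES.index("RBBB"), CLASSES.index("LBBB")
    iaf = CLASSES.index("AF")
    if prev[ir] + prev[il] > 1.0:
        raise InvalidSpecError("RBBB + LBBB prevalences sum above 1")
    u2 = rng.random(n)
    labels[:, ir] = u2 < prev[ir]
    labels[:, il] = (u2 >= prev[ir]) & (u2 < prev[ir] + prev[il])
    # 1dAVb only on non-AF records, at the conditional rate that keeps
    # the marginal at the request.
    p_af = prev[iaf]
    p1 = prev[i1] / (1.0 - p_af) if p_af < 1.0 else 0.0
    if p1 > 1.0:
        raise InvalidSpecError("1dAVb prevalence unreachable given the AF rate")
    labels[:, i1] = (rng.random(n) < p1) & ~labels[:, iaf]
    return labels


#: Per-class prevalence defaults matching the source study's training
#: population: 1dAVb 1.5%, RBBB 2.7%, LBBB 1.7%, SB 1.6%, AF 1.8%, ST 2.1%.
DEFAULT_PREVALENCES: tuple[float, ...] = (0.015, 0.027, 0.017, 0.016, 0.018, 0.021)


def generate_dataset(
    n: int,
    prevalences: Sequence[float] = DEFAULT_PREVALENCES,
    seed: int = 0,
    out_h5: Optional[str] = None,
    out_csv: Optional[str] = None,
    duration_range: tuple[float, float] = (7.0, 10.0),
    fs_choices: Sequence[float] = (300.0, 400.0, 500.0, 600.0),
    noise_sd: float = 0.01,
    baseline_amp: float = 0.05,
) -> tuple[list[ECGRecord], np.ndarray, list[MeasurementSet]]:
    """Generate ``n`` records; optionally write the HDF5+CSV container.

    Per-record seeds are derived from ``seed`` so the whole dataset is
    reproducible.  Returns the records, the n x 6 label matrix and the
    ground-truth measurements.
    """
    if not n > 0:
        raise InvalidSpecError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    labels = sample_label_matrix(n, prevalences, rng)
    durations = rng.uniform(*duration_range, size=n)
    fss = rng.choice(np.asarray(fs_choices, float), size=n)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    records: list[ECGRecord] = []
    measurements: list[MeasurementSet] = []
    for i in range(n):
        spec = SyntheticRecordSpec(
            labels=labels[i],
            duration=float(durations[i]),
            fs=float(fss[i]),
            seed=int(sub_seeds[i]),
            noise_sd=noise_sd,
            baseline_amp=baseline_amp,
        )
        rec, _, meas = synthesize_record(spec)
        rec.exam_id = f"syn{i:06d}"
        rec.patient_id = f"pat{i:06d}"
        rec.age = float(rng.integers(16, 90))
        rec.sex = "F" if rng.random() < 0.6 else "M"
        rec.acquisition_date = f"2016-{1 + i % 12:02d}-{1 + (i // 12) % 28:02d}"
        records.append(rec)
        measurements.append(meas)
    if out_h5 is not None or out_csv is not None:
        from ecgdx.container import write_dataset

        write_dataset(out_h5, out_csv, records, labels, measurements)
    return records, labels, measurements
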