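"""Weak-supervision label construction from free-text reports.

Three stages turn a cardiologist's free-text report into a candidate
label vector: n-gram feature extraction after stop-word removal, a lazy
associative classifier (association rules mined on demand from the
training corpus projected onto the query's features), and a rule-based
disambiguation step (mutually exclusive rhythm classes, negation cues).

A separate harmonization engine then combines, per exam, the expert
text label with two automatic classifiers and interval measurements:

* stage 1 — agreement: accept when the expert and at least one
  automatic source agree on an abnormality; reject when a single
  automatic source stands alone against both the expert and the other
  source;
* stage 2 — measurement-based rejections on whatever stage 1 left
  undecided: sinus tachycardia with heart rate below 100 bpm, sinus
  bradycardia with rate above 50 bpm, bundle branch block with QRS
  below 115 ms, first-degree AV block with PR below 190 ms;
* stage 3 — acceptances on the remainder: expert-positive RBBB, 1dAVb,
  SB and ST are accepted outright; expert-positive AF additionally
  requires the NN-interval standard deviation to exceed 646 (threshold
  configurable; its unit is device-specific and deliberately not
  asserted).

Anything still undecided lands in the manual-review queue.  All
boundaries are strict inequalities, read literally from their wording
("below 100" leaves exactly 100 standing, and so on).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ecgdx.records import CLASSES, RHYTHM_CLASSES, MeasurementSet, labels_to_array

# ---------------------------------------------------------------------------
# Text preprocessing

DEFAULT_STOPWORDS = frozenset(
    "de do da dos das o a os as e em com para por um uma no na ao à the of and in".split()
)


@dataclass
class TextReport:
    exam_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError(f"report {self.exam_id!r} has empty text")


def tokenize(text: str) -> list[str]:
    """Lower-case tokens with punctuation stripped (accents preserved)."""
    return re.findall(r"[^\W\d_]+", text.lower(), flags=re.UNICODE)


def preprocess_text(
    report: TextReport | str,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    n: int = 2,
) -> frozenset[str]:
    """Feature set of all contiguous n-grams up to order ``n``.

    Stop-words are removed *before* n-gram formation, so grams may span
    a removed stop-word ("bloqueio de ramo" yields "bloqueio ramo").
    """
    if n < 1:
        raise ValueError(f"n-gram order must be >= 1, got {n}")
    text = report.text if isinstance(report, TextReport) else report
    stop = set(stopwords)
    toks = [t for t in tokenize(text) if t not in stop]
    feats: set[str] = set()
    for order in range(1, n + 1):
        for i in range(len(toks) - order + 1):
            feats.add(" ".join(toks[i : i + order]))
    return frozenset(feats)


# ---------------------------------------------------------------------------
# Lazy associative classification

@dataclass
class LacModel:
    """Training corpus plus rule-mining parameters.

    ``docs`` holds (feature set, class labels) pairs; ``min_support`` is
    a fraction of the corpus, ``min_confidence`` a fraction of the
    antecedent's support.  ``max_antecedent`` caps rule length (lazy
    projection keeps mining cheap, but rule space is still exponential
    in antecedent size).
    """

    docs: list[tuple[frozenset[str], frozenset[str]]] = field(default_factory=list)
    min_support: float = 0.01
    min_confidence: float = 0.5
    max_antecedent: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError("min_support must be in (0, 1]")
        if not 0.0 < self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in (0, 1]")

    def add(self, features: Iterable[str], classes: Iterable[str]) -> None:
        self.docs.append((frozenset(features), frozenset(classes)))


def lac_classify(model: LacModel, features: Iterable[str]) -> list[tuple[str, float]]:
    """Classes ranked by average confidence of matching association rules.

    Rules ``antecedent -> class`` are mined lazily: only antecedents
    that are subsets of the query features *and* occur in the training
    corpus are considered; those meeting the support and confidence
    floors vote, and each class is scored by the mean confidence of its
    rules.  Ties break by canonical class order, then alphabetically.
    Returns an empty list when no rule matches.
    """
    query = frozenset(features)
    if not model.docs or not query:
        return []
    n_docs = len(model.docs)
    # Candidate items: query features that occur somewhere in the corpus.
    corpus_feats: set[str] = set()
    for f, _ in model.docs:
        corpus_feats |= f & query
    items = sorted(corpus_feats)
    scores: dict[str, list[float]] = {}
    for size in range(1, min(model.max_antecedent, len(items)) + 1):
        for ante in itertools.combinations(items, size):
            a = frozenset(ante)
            matching = [cls for f, cls in model.docs if a <= f]
            support = len(matching) / n_docs
            if support < model.min_support or not matching:
                continue
            class_counts: dict[str, int] = {}
            for cls_set in matching:
                for c in cls_set:
                    class_counts[c] = class_counts.get(c, 0) + 1
            for c, cnt in class_counts.items():
                conf = cnt / len(matching)
                if conf >= model.min_confidence:
                    scores.setdefault(c, []).append(conf)
    def sort_key(item: tuple[str, float]):
        c, s = item
        canon = CLASSES.index(c) if c in CLASSES else len(CLASSES)
        return (-s, canon, c)
    ranked = sorted(((c, float(np.mean(v))) for c, v in scores.items()), key=sort_key)
    return ranked


# ---------------------------------------------------------------------------
# Disambiguation

#: Trigger phrases per class, shared with the synthetic report generator.
CLASS_PHRASES: dict[str, tuple[str, ...]] = {
    "1dAVb": (
        "bloqueio atrioventricular de primeiro grau",
        "bav de primeiro grau",
        "intervalo pr prolongado",
    ),
    "RBBB": ("bloqueio completo de ramo direito", "bloqueio de ramo direito"),
    "LBBB": ("bloqueio completo de ramo esquerdo", "bloqueio de ramo esquerdo"),
    "SB": ("bradicardia sinusal",),
    "AF": ("fibrilacao atrial", "ritmo de fibrilacao atrial"),
    "ST": ("taquicardia sinusal",),
}

NORMAL_PHRASES: tuple[str, ...] = (
    "eletrocardiograma dentro dos limites da normalidade",
    "ritmo sinusal tracado normal",
    "exame sem alteracoes",
)

DEFAULT_NEGATION_CUES: tuple[str, ...] = ("sem", "ausencia", "ausência", "nao", "não", "afastado")


def _negated_classes(text: str, cues: Sequence[str], window: int = 3) -> set[str]:
    """Classes whose trigger phrase is preceded by a negation cue within
    ``window`` tokens."""
    toks = tokenize(text)
    negated: set[str] = set()
    for cls, phrases in CLASS_PHRASES.items():
        for phrase in phrases:
            ptoks = tokenize(phrase)
            for i in range(len(toks) - len(ptoks) + 1):
                if toks[i : i + len(ptoks)] == ptoks:
                    ctx = toks[max(0, i - window) : i]
                    if any(c in ctx for c in cues):
                        negated.add(cls)
    return negated


def disambiguate(
    scored: Sequence[tuple[str, float]],
    text: Optional[str] = None,
    confidence_threshold: float = 0.6,
    negation_cues: Sequence[str] = DEFAULT_NEGATION_CUES,
) -> np.ndarray:
    """Resolve scored candidates into a six-class boolean vector.

    Rules (a documented stand-in; the real pipeline's rule content is
    private): classes below ``confidence_threshold`` are dropped;
    negated mentions in the source text suppress a class; among the
    mutually exclusive rhythm classes only the highest-confidence
    survivor is kept (first in canonical order on ties).
    """
    out = np.zeros(len(CLASSES), dtype=bool)
    kept = {c: s for c, s in scored if c in CLASSES and s >= confidence_threshold}
    if text is not None:
        for c in _negated_classes(text, negation_cues):
            kept.pop(c, None)
    rhythm = [(c, kept[c]) for c in RHYTHM_CLASSES if c in kept]
    if len(rhythm) > 1:
        best = max(rhythm, key=lambda cs: (cs[1], -RHYTHM_CLASSES.index(cs[0])))
        for c, _ in rhythm:
            if c != best[0]:
                kept.pop(c)
    for c in kept:
        out[CLASSES.index(c)] = True
    return out


def extract_labels(
    report: TextReport,
    model: LacModel,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    n: int = 2,
    confidence_threshold: float = 0.6,
) -> np.ndarray:
    """Full text pipeline: features -> lazy classification -> disambiguation."""
    feats = preprocess_text(report, stopwords, n)
    scored = lac_classify(model, feats) if feats else []
    return disambiguate(scored, text=report.text, confidence_threshold=confidence_threshold)


# ---------------------------------------------------------------------------
# Harmonization

@dataclass
class RuleThresholds:
    """Measurement boundaries of the harmonization rules.  All strict."""

    st_hr: float = 100.0  # reject ST below this heart rate (bpm)
    sb_hr: float = 50.0  # reject SB above this heart rate (bpm)
    bbb_qrs: float = 115.0  # reject RBBB/LBBB below this QRS duration (ms)
    avb_pr: float = 190.0  # reject 1dAVb below this PR interval (ms)
    af_sdnn: float = 646.0  # accept AF only above this SDNN (unit unasserted)


@dataclass
class AnnotationBundle:
    """Per-exam annotations entering harmonization: the expert text
    label and two automatic classifiers, plus interval measurements."""

    exam_id: str
    expert: np.ndarray
    unig: np.ndarray
    minnesota: np.ndarray
    measurements: MeasurementSet = field(default_factory=MeasurementSet)

    def __post_init__(self) -> None:
        for name in ("expert", "unig", "minnesota"):
            v = getattr(self, name)
            try:
                setattr(self, name, labels_to_array(v))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"bundle field {name!r} malformed: {exc}") from exc
        if not isinstance(self.measurements, MeasurementSet):
            raise ValueError("bundle field 'measurements' must be a MeasurementSet")


@dataclass
class HarmonizationResult:
    """Per-class decision plus the identifier of the rule that fired."""

    exam_id: str
    status: dict[str, str]
    rule_id: dict[str, str]


ACCEPTED, REJECTED, NEEDS_REVIEW = "accepted", "rejected", "needs_review"


def harmonize(
    bundle: AnnotationBundle, thresholds: RuleThresholds | None = None
) -> HarmonizationResult:
    """Run the three-stage accept/reject logic on one exam.

    Stage-1 decisions are final; measurement rules (stage 2) and
    expert-based acceptances (stage 3) apply only to classes the
    agreement logic left undecided.  Missing measurements make the
    corresponding stage-2 rule non-firing (conservative) and block the
    SDNN-gated AF acceptance.
    """
    thr = thresholds or RuleThresholds()
    m = bundle.measurements
    status: dict[str, str] = {}
    rule: dict[str, str] = {}
    for i, cls in enumerate(CLASSES):
        e = bool(bundle.expert[i])
        u = bool(bundle.unig[i])
        mn = bool(bundle.minnesota[i])
        # Stage 0/1: agreement logic.
        if not (e or u or mn):
            status[cls], rule[cls] = REJECTED, "S0-absent"
            continue
        if e and (u or mn):
            status[cls], rule[cls] = ACCEPTED, "S1-accept-expert-auto-agree"
            continue
        if not e and (u != mn):  # exactly one automatic source stands alone
            status[cls], rule[cls] = REJECTED, "S1-reject-lone-automatic"
            continue
        # Stage 2: measurement-based rejections.
        hr, qrs, pr, sdnn = m.heart_rate, m.qrs_duration, m.pr_interval, m.sdnn
        if cls == "ST" and np.isfinite(hr) and hr < thr.st_hr:
            status[cls], rule[cls] = REJECTED, "S2-reject-ST-HR-low"
            continue
        if cls == "SB" and np.isfinite(hr) and hr > thr.sb_hr:
            status[cls], rule[cls] = REJECTED, "S2-reject-SB-HR-high"
            continue
        if cls in ("RBBB", "LBBB") and np.isfinite(qrs) and qrs < thr.bbb_qrs:
            status[cls], rule[cls] = REJECTED, "S2-reject-BBB-QRS-narrow"
            continue
        if cls == "1dAVb" and np.isfinite(pr) and pr < thr.avb_pr:
            status[cls], rule[cls] = REJECTED, "S2-reject-1dAVb-PR-short"
            continue
        # Stage 3: acceptances.
        if cls in ("RBBB", "1dAVb", "SB", "ST") and e:
            status[cls], rule[cls] = ACCEPTED, "S3-accept-expert"
            continue
        if cls == "AF" and e and np.isfinite(sdnn) and sdnn > thr.af_sdnn:
            status[cls], rule[cls] = ACCEPTED, "S3-accept-AF-SDNN"
            continue
        status[cls], rule[cls] = NEEDS_REVIEW, "undecided"
    return HarmonizationResult(exam_id=bundle.exam_id, status=status, rule_id=rule)


def review_queue(results: Sequence[HarmonizationResult]) -> pd.DataFrame:
    """Exam x class pairs still needing manual review, with the audit trail."""
    rows = [
        {"exam_id": r.exam_id, "class": cls, "status": NEEDS_REVIEW, "rule_id": r.rule_id[cls]}
        for r in results
        for cls in CLASSES
        if r.status[cls] == NEEDS_REVIEW
    ]
    return pd.DataFrame(rows, columns=["exam_id", "class", "status", "rule_id"])


# ---------------------------------------------------------------------------
# Synthetic report generator (testing stand-in; the study's report corpus
# is private)

def generate_report(labels, rng: np.random.Generator, include_negations: bool = True) -> str:
    """Templated Portuguese report for a label vector."""
    vec = labels_to_array(labels)
    parts: list[str] = []
    positives = [c for i, c in enumerate(CLASSES) if vec[i]]
    if not positives:
        parts.append(NORMAL_PHRASES[rng.integers(len(NORMAL_PHRASES))])
    else:
        if not any(c in positives for c in RHYTHM_CLASSES):
            parts.append("ritmo sinusal")
        for c in positives:
            phrases = CLASS_PHRASES[c]
            parts.append(phrases[rng.integers(len(phrases))])
        if include_negations and rng.random() < 0.3:
            absent = [c for c in CLASSES if c not in positives]
            if absent:
                c = absent[rng.integers(len(absent))]
                parts.append("sem " + CLASS_PHRASES[c][0])
    return ". ".join(p.capitalize() for p in parts) + "."


def build_synthetic_lac_model(
    n_docs: int = 400,
    seed: int = 0,
    min_support: float = 0.01,
    min_confidence: float = 0.5,
    max_antecedent: int = 2,
) -> LacModel:
    """Train a lazy associative classifier on generated reports."""
    from ecgdx.synthetic import sample_label_matrix

    rng = np.random.default_rng(seed)
    prev = np.full(len(CLASSES), 0.15)
    labels = sample_label_matrix(n_docs, prev, rng)
    model = LacModel(
        min_support=min_support, min_confidence=min_confidence, max_antecedent=max_antecedent
    )
    for i in range(n_docs):
        text = generate_report(labels[i], rng, include_negations=False)
        feats = preprocess_text(text)
        model.add(feats, [c for j, c in enumerate(CLASSES) if labels[i, j]])
    return model
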