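"""Precision / recall / F1 scoring for relaxed and exact NER evaluation.

Two regimes are supported:

* **relaxed** — operates on label pairs produced by
  :mod:`promptner.alignment` (or loaded from a pair CSV): a prediction
  counts as correct when the paired labels agree, regardless of exact
  boundaries.  Per-label counts come from the (K+1)×(K+1) true ×
  predicted confusion matrix with the ``O`` sentinel included.
* **exact** — operates on document pairs or BIO streams: a predicted
  entity counts only with identical (start, end, label).  The
  chunk-based variant (:func:`seqeval_style_metrics`) extracts entity
  chunks from BIO tags and scores chunk identity.

All metrics use F1 = 2·P·R/(P+R) with the convention that a zero
denominator yields 0.  Display rounding is half-up to two decimals;
internal values keep full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ALL_CLASSES, AnnotatedDocument, InvariantError, LabelPair, O
from .interchange import BIOSequence

__all__ = [
    "f1_from_counts",
    "ClassCounts",
    "ConfusionMatrix",
    "confusion_matrix",
    "ScoreReport",
    "classification_metrics",
    "exact_match_metrics",
    "seqeval_style_metrics",
    "extract_chunks",
    "round_half_up",
    "render_report",
    "ScoringWarning",
]


class ScoringWarning(UserWarning):
    """Degenerate scoring situations (zero denominators, repaired tags)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed report tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def f1_from_counts(
    tp: int, fp: int, fn: int, *, zero_division: str = "zero"
) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts.

    ``zero_division`` is ``"zero"`` (0 with a warning, the default) or
    ``"raise"``.
    """
    if min(tp, fp, fn) < 0:
        raise InvariantError(f"counts must be non-negative, got {(tp, fp, fn)}")

    def _ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            if zero_division == "raise":
                raise ZeroDivisionError(f"{what} undefined: zero denominator")
            warnings.warn(
                f"{what} has zero denominator; reporting 0", ScoringWarning,
                stacklevel=3,
            )
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest counts for a single label."""

    label: str
    tp: int
    fp: int
    fn: int
    tn: int = 0

    @property
    def support(self) -> int:
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class ConfusionMatrix:
    """True × predicted label counts over a pair multiset."""

    def __init__(self, labels: Sequence[str], counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(labels), len(labels)):
            raise InvariantError("counts must be square over labels")
        if (counts < 0).any():
            raise InvariantError("counts must be non-negative")
        self.labels = tuple(labels)
        self.counts = counts

    def __getitem__(self, key: tuple[str, str]) -> int:
        t, p = key
        return int(self.counts[self.labels.index(t), self.labels.index(p)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else 0.0

    def class_counts(self, label: str) -> ClassCounts:
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return ClassCounts(label, tp, fp, fn, tn)

    def transposed(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.labels, self.counts.T.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConfusionMatrix)
            and self.labels == other.labels
            and bool((self.counts == other.counts).all())
        )


def confusion_matrix(
    pairs: Sequence[LabelPair], labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count pair rows into a confusion matrix.

    ``labels`` defaults to the canonical sorted class list (entities
    plus ``O``); pairs carrying a label outside it raise.
    """
    labs = tuple(labels) if labels is not None else ALL_CLASSES
    index = {lab: i for i, lab in enumerate(labs)}
    counts = np.zeros((len(labs), len(labs)), dtype=np.int64)
    for pair in pairs:
        try:
            counts[index[pair.y_true], index[pair.y_pred]] += 1
        except KeyError as err:
            raise InvariantError(f"label {err.args[0]!r} not in matrix labels") from err
    return ConfusionMatrix(labs, counts)


@dataclass(frozen=True)
class LabelMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ScoreReport:
    """Per-label and aggregate metrics for one evaluation run."""

    per_label: Mapping[str, LabelMetrics]
    accuracy: float
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]
    total_support: int
    include_O: bool
    counts: Mapping[str, ClassCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {
            lab: {
                "precision": m.precision,
                "recall": m.recall,
                "f1-score": m.f1,
                "support": m.support,
            }
            for lab, m in self.per_label.items()
        }
        d["accuracy"] = self.accuracy
        for name, (p, r, f1) in (
            ("macro avg", self.macro_avg),
            ("weighted avg", self.weighted_avg),
        ):
            d[name] = {
                "precision": p,
                "recall": r,
                "f1-score": f1,
                "support": self.total_support,
            }
        d["include_O"] = self.include_O
        return d


def _report_from_counts(
    counts: Sequence[ClassCounts],
    accuracy: float,
    total_support: int,
    include_O: bool,
) -> ScoreReport:
    per_label: dict[str, LabelMetrics] = {}
    for c in counts:
        p, r, f1 = f1_from_counts(c.tp, c.fp, c.fn)
        per_label[c.label] = LabelMetrics(p, r, f1, c.support)
    k = len(per_label)
    if k:
        macro = tuple(
            sum(getattr(m, a) for m in per_label.values()) / k
            for a in ("precision", "recall", "f1")
        )
        w_total = sum(m.support for m in per_label.values())
        if w_total:
            weighted = tuple(
                sum(getattr(m, a) * m.support for m in per_label.values()) / w_total
                for a in ("precision", "recall", "f1")
            )
        else:
            weighted = (0.0, 0.0, 0.0)
    else:
        macro = weighted = (0.0, 0.0, 0.0)
    return ScoreReport(
        per_label=per_label,
        accuracy=accuracy,
        macro_avg=macro,  # type: ignore[arg-type]
        weighted_avg=weighted,  # type: ignore[arg-type]
        total_support=total_support,
        include_O=include_O,
        counts={c.label: c for c in counts},
    )


def classification_metrics(
    pairs: Sequence[LabelPair], include_O: bool = True
) -> ScoreReport:
    """Relaxed-match metrics over a label-pair multiset.

    Per-label precision/recall/F1 derive from the confusion matrix;
    accuracy is the fraction of agreeing pairs over *all* pairs; macro
    and weighted averages run over the included labels (``O`` dropped
    when ``include_O`` is false).
    """
    if not pairs:
        raise InvariantError("cannot score an empty pair list")
    observed = sorted({p.y_true for p in pairs} | {p.y_pred for p in pairs})
    cm = confusion_matrix(pairs, labels=observed)
    included = [lab for lab in observed if include_O or lab != O]
    counts = [cm.class_counts(lab) for lab in included]
    return _report_from_counts(
        counts,
        accuracy=cm.accuracy,
        total_support=cm.total,
        include_O=include_O,
    )


def _span_counts(
    reference_docs: Sequence[AnnotatedDocument],
    predicted_docs: Sequence[AnnotatedDocument],
) -> dict[str, ClassCounts]:
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    for ref, pred in zip(reference_docs, predicted_docs, strict=True):
        if ref.text != pred.text:
            raise InvariantError(
                f"document texts differ: {ref.doc_id!r} vs {pred.doc_id!r}"
            )
        ref_set = set(ref.spans)
        pred_set = set(pred.spans)
        for sp in ref_set & pred_set:
            tp[sp.label] = tp.get(sp.label, 0) + 1
        for sp in pred_set - ref_set:
            fp[sp.label] = fp.get(sp.label, 0) + 1
        for sp in ref_set - pred_set:
            fn[sp.label] = fn.get(sp.label, 0) + 1
    labels = sorted(set(tp) | set(fp) | set(fn))
    return {
        lab: ClassCounts(lab, tp.get(lab, 0), fp.get(lab, 0), fn.get(lab, 0))
        for lab in labels
    }


def _micro_report(counts: dict[str, ClassCounts]) -> ScoreReport:
    tp = sum(c.tp for c in counts.values())
    fp = sum(c.fp for c in counts.values())
    fn = sum(c.fn for c in counts.values())
    denom = tp + fp + fn
    accuracy = tp / denom if denom else 0.0
    return _report_from_counts(
        list(counts.values()),
        accuracy=accuracy,
        total_support=tp + fn,
        include_O=False,
    )


def exact_match_metrics(
    reference_docs: Sequence[AnnotatedDocument],
    predicted_docs: Sequence[AnnotatedDocument],
    include_O: bool = False,
) -> ScoreReport:
    """Exact-match entity metrics over paired document sets.

    A predicted span is a true positive iff a reference span with
    identical (start, end, label) exists in the same document.  The
    reported accuracy is the micro ratio TP/(TP+FP+FN).  There is no
    ``O`` row in this regime; ``include_O`` is recorded for symmetry
    with the relaxed report and has no further effect.
    """
    if include_O:
        warnings.warn(
            "exact-match scoring has no O row; include_O ignored",
            ScoringWarning,
            stacklevel=2,
        )
    return _micro_report(_span_counts(reference_docs, predicted_docs))


Chunk = tuple[int, int, int, str]  # (sequence index, first token, last token+1, label)


def extract_chunks(
    seqs: Sequence[BIOSequence], *, strict: bool = False
) -> set[Chunk]:
    """Entity chunks encoded by BIO streams.

    An ``I-`` tag that does not continue a chunk of the same label is
    repaired by promotion to ``B-`` (with a warning); ``strict=True``
    raises instead.
    """
    chunks: set[Chunk] = set()
    for s, seq in enumerate(seqs):
        open_label = ""
        start = -1
        for t, tag in enumerate(seq.tags):
            if tag.startswith("I-") and tag[2:] == open_label:
                continue
            if tag.startswith("I-"):
                if strict:
                    raise InvariantError(
                        f"sequence {s}: dangling {tag} at token {t}"
                    )
                warnings.warn(
                    f"sequence {s}: promoting dangling {tag} to B-{tag[2:]}",
                    ScoringWarning,
                    stacklevel=2,
                )
            if open_label:
                chunks.add((s, start, t, open_label))
            open_label = tag[2:] if tag != O else ""
            start = t
        if open_label:
            chunks.add((s, start, len(seq.tags), open_label))
    return chunks


def seqeval_style_metrics(
    true_bio: Sequence[BIOSequence],
    pred_bio: Sequence[BIOSequence],
    *,
    strict: bool = False,
) -> ScoreReport:
    """Chunk-level metrics over parallel BIO streams.

    A predicted chunk counts only when an identically-bounded,
    identically-labelled true chunk exists, mirroring exact span
    matching at the token level.
    """
    if len(true_bio) != len(pred_bio):
        raise InvariantError("true and predicted streams differ in sequence count")
    for s, (a, b) in enumerate(zip(true_bio, pred_bio)):
        if len(a) != len(b):
            raise InvariantError(f"sequence {s}: token counts differ")
    true_chunks = extract_chunks(true_bio, strict=strict)
    pred_chunks = extract_chunks(pred_bio, strict=strict)
    labels = sorted({c[3] for c in true_chunks | pred_chunks})
    counts = {}
    for lab in labels:
        t = {c for c in true_chunks if c[3] == lab}
        p = {c for c in pred_chunks if c[3] == lab}
        counts[lab] = ClassCounts(lab, len(t & p), len(p - t), len(t - p))
    return _micro_report(counts)


def render_report(report: ScoreReport, ndigits: int = 2) -> str:
    """Plain-text metrics table in classification-report layout."""
    width = max([len(lab) for lab in report.per_label] + [len("weighted avg")])
    header = f"{'':>{width}}  {'precision':>9}  {'recall':>9}  {'f1-score':>9}  {'support':>9}"
    lines = [header, ""]
    fmt = lambda x: f"{round_half_up(x, ndigits):>9.{ndigits}f}"  # noqa: E731
    for lab, m in report.per_label.items():
        lines.append(
            f"{lab:>{width}}  {fmt(m.precision)}  {fmt(m.recall)}  {fmt(m.f1)}  {m.support:>9}"
        )
    lines.append("")
    lines.append(
        f"{'accuracy':>{width}}  {'':>9}  {'':>9}  {fmt(report.accuracy)}  {report.total_support:>9}"
    )
    for name, triple in (
        ("macro avg", report.macro_avg),
        ("weighted avg", report.weighted_avg),
    ):
        p, r, f1 = triple
        lines.append(
            f"{name:>{width}}  {fmt(p)}  {fmt(r)}  {fmt(f1)}  {report.total_support:>9}"
        )
    return "\n".join(lines)
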