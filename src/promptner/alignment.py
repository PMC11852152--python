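"""Relaxed-match alignment of predicted against reference annotations.

A predicted entity is relaxed-correct when its type matches a reference
entity and their character spans overlap.  This module turns a
(reference, predicted) document pair into the label-pair table that
relaxed scoring consumes: each reference span is matched one-to-one
with at most one overlapping predicted span and vice versa; unmatched
spans pair with ``O``; text unannotated in both documents contributes
``(O, O)`` bookkeeping units.

Matching maximises total character overlap exactly.  Because spans
within one document are disjoint and ordered, any two candidate pairs
that "cross" (earlier reference with later prediction and vice versa)
cannot both have positive overlap, so every candidate matching is
monotone and the optimum is found by an alignment-style dynamic program
rather than a general assignment solver.  Ties are broken by preferring
more matched pairs, then the lexicographically earliest (reference,
predicted) index sequence; this tie-break is invariant under swapping
the two documents, which makes the alignment exactly symmetric (the
confusion matrix transposes).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AnnotatedDocument, InvariantError, LabelPair, O, Span
from .interchange import tokenize

__all__ = ["MatchConfig", "align_entities"]


@dataclass(frozen=True)
class MatchConfig:
    """Alignment parameters.

    overlap_rule
        Minimum number of shared characters for two spans to be
        matchable (default 1: any overlap).
    o_unit
        Granularity at which unannotated text is counted as ``(O, O)``
        units: ``"token"`` (default) or ``"run"`` (one unit per maximal
        unannotated stretch).
    tie_break
        Identifier of the deterministic tie-break; only
        ``"earliest"`` is defined.
    """

    overlap_rule: int = 1
    o_unit: str = "token"
    tie_break: str = "earliest"

    def __post_init__(self) -> None:
        if self.overlap_rule < 1:
            raise InvariantError("overlap_rule must be >= 1")
        if self.o_unit not in ("token", "run"):
            raise InvariantError(f"unknown o_unit {self.o_unit!r}")
        if self.tie_break != "earliest":
            raise InvariantError(f"unknown tie_break {self.tie_break!r}")


_Value = tuple[int, int, tuple[tuple[int, int], ...]]
# (total overlap, matched count, matched index pairs); compared by
# max overlap, then max count, then lexicographically SMALLEST pair list.


def _better(a: _Value, b: _Value) -> _Value:
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    if a[1] != b[1]:
        return a if a[1] > b[1] else b
    return a if a[2] <= b[2] else b


def _optimal_matching(
    ref: tuple[Span, ...], pred: tuple[Span, ...], min_overlap: int
) -> tuple[tuple[int, int], ...]:
    """Maximum-total-overlap one-to-one matching between two span lists."""
    n, m = len(ref), len(pred)
    # value[i][j] = best matching for suffixes ref[i:], pred[j:]
    empty: _Value = (0, 0, ())
    value = [[empty] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            best = _better(value[i + 1][j], value[i][j + 1])
            ov = ref[i].overlap(pred[j])
            if ov >= min_overlap:
                sub = value[i + 1][j + 1]
                cand: _Value = (ov + sub[0], 1 + sub[1], ((i, j),) + sub[2])
                best = _better(cand, best)
            value[i][j] = best
    return value[0][0][2]


def align_entities(
    reference: AnnotatedDocument,
    predicted: AnnotatedDocument,
    config: MatchConfig = MatchConfig(),
) -> list[LabelPair]:
    """Produce the relaxed-match label-pair table for one document pair.

    Both documents must carry identical text.  Matched spans yield one
    ``(reference label, predicted label)`` row (so a label confusion on
    overlapping spans is a single row, not two ``O`` rows); unmatched
    reference spans yield ``(label, O)``, unmatched predicted spans
    ``(O, label)``, and text outside all spans in both documents yields
    ``(O, O)`` units at ``config.o_unit`` granularity.  Rows are ordered
    by character position.  A ``Compare`` column records agreement.
    """
    if reference.text != predicted.text:
        raise InvariantError(
            f"document texts differ: {reference.doc_id!r} vs {predicted.doc_id!r}"
        )
    matches = _optimal_matching(reference.spans, predicted.spans, config.overlap_rule)
    matched_ref = {i for i, _ in matches}
    matched_pred = {j for _, j in matches}

    rows: list[tuple[int, LabelPair]] = []
    doc_id = reference.doc_id

    def add(position: int, surface: str, y_true: str, y_pred: str) -> None:
        compare = "TRUE" if y_true == y_pred else "FALSE"
        rows.append(
            (
                position,
                LabelPair(doc_id, surface, y_true, y_pred, extra=(("Compare", compare),)),
            )
        )

    for i, j in matches:
        rsp, psp = reference.spans[i], predicted.spans[j]
        add(rsp.start, reference.surface(rsp), rsp.label, psp.label)
    for i, rsp in enumerate(reference.spans):
        if i not in matched_ref:
            add(rsp.start, reference.surface(rsp), rsp.label, O)
    for j, psp in enumerate(predicted.spans):
        if j not in matched_pred:
            add(psp.start, predicted.surface(psp), O, psp.label)

    for start, end in _unannotated_segments(reference, predicted):
        if config.o_unit == "token":
            for tok in tokenize(reference.text[start:end]):
                add(start + tok.start, tok.surface, O, O)
        else:
            surface = reference.text[start:end].strip()
            if surface:
                add(start, surface, O, O)

    rows.sort(key=lambda item: item[0])
    return [pair for _, pair in rows]


def _unannotated_segments(
    reference: AnnotatedDocument, predicted: AnnotatedDocument
) -> list[tuple[int, int]]:
    """Maximal text segments covered by no span of either document."""
    boundaries = sorted(
        {0, len(reference.text)}
        | {sp.start for sp in reference.spans + predicted.spans}
        | {sp.end for sp in reference.spans + predicted.spans}
    )
    covered = reference.spans + predicted.spans
    segments: list[tuple[int, int]] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        if any(sp.start < hi and sp.end > lo for sp in covered):
            continue
        if segments and segments[-1][1] == lo:
            segments[-1] = (segments[-1][0], hi)
        else:
            segments.append((lo, hi))
    return segments
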