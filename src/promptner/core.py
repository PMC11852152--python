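"""Core domain types for span-annotated clinical reports.

The annotation schema is flat: a report is plain text plus a list of
non-overlapping, non-nested labeled character spans.  Five entity classes
are recognised (anatomy, impression, and present / absent / uncertain
observations); ``O`` is the reserved non-entity sentinel used in
evaluation rows and BIO tags but never attached to a span.

All offsets are 0-based, half-open, and counted in Unicode code points.
No case folding is ever applied (Turkish dotted/dotless *i* must survive
untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "LABELS",
    "O",
    "ALL_CLASSES",
    "Span",
    "AnnotatedDocument",
    "Token",
    "LabelPair",
    "InvalidLabelError",
    "InvariantError",
]

#: The closed, case-sensitive set of entity labels.
LABELS: tuple[str, ...] = ("ANAT", "IMP", "OBS-P", "OBS-A", "OBS-U")

#: Non-entity sentinel: tags unannotated tokens, never a span label.
O: str = "O"

#: Evaluation classes in canonical (sorted) order: entities plus O.
ALL_CLASSES: tuple[str, ...] = tuple(sorted((*LABELS, O)))


class InvalidLabelError(ValueError):
    """An entity label outside the closed schema was encountered."""


class InvariantError(ValueError):
    """A domain-type invariant (ordering, overlap, bounds) was violated."""


def check_label(name: str) -> str:
    """Validate *name* against the closed entity-label set and return it."""
    if name not in LABELS:
        raise InvalidLabelError(
            f"unknown entity label {name!r}; expected one of {', '.join(LABELS)}"
        )
    return name


@dataclass(frozen=True, order=True)
class Span:
    """A labeled character span: ``text[start:end]`` carries ``label``."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvariantError(
                f"span offsets must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )
        check_label(self.label)

    def overlap(self, other: "Span") -> int:
        """Number of characters shared with *other*."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, delta: int) -> "Span":
        return Span(self.start + delta, self.end + delta, self.label)


@dataclass(frozen=True)
class AnnotatedDocument:
    """A report text with sorted, non-overlapping, non-nested entity spans."""

    doc_id: str
    text: str
    spans: tuple[Span, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", tuple(self.spans))
        prev_end = 0
        for sp in self.spans:
            if sp.end > len(self.text):
                raise InvariantError(
                    f"{self.doc_id}: span [{sp.start}, {sp.end}) exceeds text length {len(self.text)}"
                )
            if sp.start < prev_end:
                raise InvariantError(
                    f"{self.doc_id}: spans overlap or are unsorted at [{sp.start}, {sp.end})"
                )
            prev_end = sp.end

    def surface(self, span: Span) -> str:
        return self.text[span.start : span.end]

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(self.surface(sp) for sp in self.spans)

    def with_spans(self, spans: Iterable[Span]) -> "AnnotatedDocument":
        """Same text and id, new (re-sorted) span set."""
        return AnnotatedDocument(self.doc_id, self.text, tuple(sorted(spans)))


@dataclass(frozen=True)
class Token:
    """One tokenizer unit with its character offsets into the document."""

    surface: str
    start: int
    end: int


@dataclass(frozen=True)
class LabelPair:
    """One evaluation row: a true/predicted label pair over a surface.

    This mirrors one line of the relaxed-match pair table
    (``doc_id;surface;y_true;y_pred;Compare``).  ``O`` on one side means
    the other side's entity had no counterpart; ``(O, O)`` rows are the
    unannotated-text bookkeeping units.
    """

    doc_id: str
    surface: str
    y_true: str
    y_pred: str
    extra: tuple[tuple[str, str], ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for lab in (self.y_true, self.y_pred):
            if lab != O:
                check_label(lab)

    @property
    def agree(self) -> bool:
        return self.y_true == self.y_pred


def spans_non_overlapping(spans: Sequence[Span]) -> bool:
    """True when the (sorted) spans neither overlap nor nest."""
    ordered = sorted(spans)
    return all(a.end <= b.start for a, b in zip(ordered, ordered[1:]))
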