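"""Format interchange: JSONL records, BIO sequences, and pair tables.

This module moves annotations between the representations the pipeline
uses: annotation-platform JSONL (text plus ``[start, end, label]``
triples), token-level BIO tag streams for chunk-based evaluation, and
the delimited label-pair table that relaxed-match scoring consumes.

The tokenizer is intentionally simple — whitespace split, then leading
and trailing punctuation detached as standalone tokens — which matches
the preprocessing requirement that marks like ``-`` in
``atelectasis -infarction`` become their own tokens before exact-match
tokenized evaluation.
"""

from __future__ import annotations

import json
import unicodedata
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    AnnotatedDocument,
    InvariantError,
    LABELS,
    LabelPair,
    O,
    Span,
    Token,
    check_label,
)

__all__ = [
    "tokenize",
    "detach_punctuation",
    "to_jsonl_record",
    "from_jsonl_record",
    "read_jsonl",
    "write_jsonl",
    "BIOSequence",
    "doc_to_bio",
    "bio_to_spans",
    "pairs_to_bio",
    "read_bio",
    "write_bio",
    "read_pairs",
    "write_pairs",
    "pairs_to_frame",
]


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenization with punctuation detached at token edges.

    Leading and trailing punctuation characters of each whitespace chunk
    become standalone single-character tokens, so ``"atelectasis
    -infarction"`` yields ``atelectasis``, ``-``, ``infarction``.
    Offsets index the original text; concatenating surfaces with the
    original inter-token gaps reconstructs it.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        lo, hi = i, j
        while lo < hi and _is_punct(text[lo]):
            tokens.append(Token(text[lo], lo, lo + 1))
            lo += 1
        trailing: list[Token] = []
        while hi > lo and _is_punct(text[hi - 1]):
            trailing.append(Token(text[hi - 1], hi - 1, hi))
            hi -= 1
        if lo < hi:
            tokens.append(Token(text[lo:hi], lo, hi))
        tokens.extend(reversed(trailing))
        i = j
    return tokens


def detach_punctuation(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Insert whitespace between span boundaries and adjacent punctuation.

    Needed upstream of exact-match tokenized evaluation only: a span
    boundary butting against punctuation (``…is -infarction`` with the
    span starting at ``infarction``) would otherwise sit mid-token for
    tokenizers that keep the mark attached.  Span surfaces are preserved;
    offsets are remapped around the inserted spaces.
    """
    cuts: set[int] = set()
    text = doc.text
    for sp in doc.spans:
        for b in (sp.start, sp.end):
            if 0 < b < len(text):
                left, right = text[b - 1], text[b]
                if (
                    not left.isspace()
                    and not right.isspace()
                    and (_is_punct(left) or _is_punct(right))
                ):
                    cuts.add(b)
    if not cuts:
        return doc
    ordered = sorted(cuts)
    pieces: list[str] = []
    prev = 0
    for c in ordered:
        pieces.append(text[prev:c])
        pieces.append(" ")
        prev = c
    pieces.append(text[prev:])
    new_text = "".join(pieces)

    def remap(offset: int, is_end: bool) -> int:
        # insertions strictly before the offset shift it; an insertion AT
        # a start offset also shifts the start (the space lands outside).
        shift = sum(1 for c in ordered if c < offset or (c == offset and not is_end))
        return offset + shift

    new_spans = tuple(
        Span(remap(sp.start, False), remap(sp.end, True), sp.label) for sp in doc.spans
    )
    return AnnotatedDocument(doc.doc_id, new_text, new_spans)


# --------------------------------------------------------------------------
# JSONL (annotation-platform dialect)
# --------------------------------------------------------------------------

def to_jsonl_record(doc: AnnotatedDocument) -> dict:
    """Document → annotation-platform record (``label`` triple list)."""
    return {
        "id": doc.doc_id,
        "text": doc.text,
        "label": [[sp.start, sp.end, sp.label] for sp in doc.spans],
    }


def from_jsonl_record(record: dict, doc_id: str | None = None) -> AnnotatedDocument:
    """Record → document.  Reads ``label`` or the alternate ``entities`` key."""
    rid = doc_id if doc_id is not None else str(record.get("id", ""))
    text = record["text"]
    triples = record.get("label", record.get("entities", []))
    spans = []
    for triple in triples:
        start, end, label = triple
        if not (0 <= start < end <= len(text)):
            raise InvariantError(
                f"{rid}: label triple {list(triple)!r} out of bounds for text of "
                f"length {len(text)}"
            )
        spans.append(Span(int(start), int(end), check_label(label)))
    return AnnotatedDocument(rid, text, tuple(sorted(spans)))


def read_jsonl(path: str | Path) -> list[AnnotatedDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if line.strip():
                rec = json.loads(line)
                docs.append(from_jsonl_record(rec, doc_id=str(rec.get("id", i))))
    return docs


def write_jsonl(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(to_jsonl_record(doc), ensure_ascii=False) + "\n")


# --------------------------------------------------------------------------
# BIO
# --------------------------------------------------------------------------

class BIOSequence:
    """Parallel token / BIO-tag lists for one sequence.

    Tags are drawn from ``{O} ∪ {B-L, I-L}`` over the entity labels;
    ``I-L`` may only continue a chunk opened by ``B-L`` (or another
    ``I-L``) of the same label.
    """

    __slots__ = ("tokens", "tags")

    def __init__(self, tokens: Sequence[str] | Sequence[Token], tags: Sequence[str]):
        toks = [t.surface if isinstance(t, Token) else t for t in tokens]
        if len(toks) != len(tags):
            raise InvariantError(
                f"token/tag length mismatch: {len(toks)} vs {len(tags)}"
            )
        for tag in tags:
            if tag != O and (tag[:2] not in ("B-", "I-") or tag[2:] not in LABELS):
                raise InvariantError(f"invalid BIO tag {tag!r}")
        self.tokens = list(toks)
        self.tags = list(tags)

    def __len__(self) -> int:
        return len(self.tags)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BIOSequence)
            and self.tokens == other.tokens
            and self.tags == other.tags
        )

    def __repr__(self) -> str:
        return f"BIOSequence({list(zip(self.tokens, self.tags))!r})"


def doc_to_bio(doc: AnnotatedDocument) -> BIOSequence:
    """Encode a document as one BIO sequence over its tokens.

    Every span must align with token boundaries (run
    :func:`detach_punctuation` first when punctuation abuts entity
    edges); a boundary that splits a token raises.
    """
    tokens = tokenize(doc.text)
    tags = [O] * len(tokens)
    ti = 0
    for sp in doc.spans:
        first = True
        for k in range(ti, len(tokens)):
            tok = tokens[k]
            if tok.end <= sp.start:
                continue
            if tok.start >= sp.end:
                ti = k
                break
            if tok.start < sp.start or tok.end > sp.end:
                raise InvariantError(
                    f"{doc.doc_id}: span [{sp.start}, {sp.end}) {sp.label} splits "
                    f"token {tok.surface!r} at [{tok.start}, {tok.end})"
                )
            tags[k] = ("B-" if first else "I-") + sp.label
            first = False
    return BIOSequence(tokens, tags)


def bio_to_spans(doc_text: str, seq: BIOSequence) -> tuple[Span, ...]:
    """Decode a BIO sequence produced from *doc_text* back to char spans."""
    tokens = tokenize(doc_text)
    if len(tokens) != len(seq):
        raise InvariantError(
            f"text tokenizes to {len(tokens)} tokens but sequence has {len(seq)}"
        )
    spans: list[Span] = []
    open_start = open_end = -1
    open_label = ""
    for tok, tag in zip(tokens, seq.tags):
        cont = tag.startswith("I-") and tag[2:] == open_label and open_start >= 0
        if cont:
            open_end = tok.end
            continue
        if open_start >= 0:
            spans.append(Span(open_start, open_end, open_label))
            open_start = -1
            open_label = ""
        if tag != O:
            open_label = tag[2:]
            open_start, open_end = tok.start, tok.end
    if open_start >= 0:
        spans.append(Span(open_start, open_end, open_label))
    return tuple(spans)


def pairs_to_bio(
    pairs: Sequence[LabelPair],
) -> tuple[list[BIOSequence], list[BIOSequence]]:
    """Expand label pairs into parallel true/predicted BIO streams.

    Each pair's surface is tokenized; its tokens receive ``B-``/``I-``
    tags of ``y_true`` in the true stream and of ``y_pred`` in the
    predicted stream (an ``O`` label maps to all-``O`` tags).  One
    sequence is emitted per pair, so chunk supports equal pair counts.
    """
    true_seqs: list[BIOSequence] = []
    pred_seqs: list[BIOSequence] = []
    for pair in pairs:
        surfaces = [t.surface for t in tokenize(pair.surface)]
        if not surfaces:
            raise InvariantError(f"{pair.doc_id}: pair has empty surface")
        true_seqs.append(BIOSequence(surfaces, _label_tags(pair.y_true, len(surfaces))))
        pred_seqs.append(BIOSequence(surfaces, _label_tags(pair.y_pred, len(surfaces))))
    return true_seqs, pred_seqs


def _label_tags(label: str, n: int) -> list[str]:
    if label == O:
        return [O] * n
    return ["B-" + label] + ["I-" + label] * (n - 1)


def read_bio(path: str | Path) -> list[BIOSequence]:
    """Read two-column BIO text (token TAB tag, blank line between sequences)."""
    seqs: list[BIOSequence] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                if toks:
                    seqs.append(BIOSequence(toks, tags))
                    toks, tags = [], []
                continue
            tok, _, tag = line.rpartition("\t")
            toks.append(tok)
            tags.append(tag)
    if toks:
        seqs.append(BIOSequence(toks, tags))
    return seqs


def write_bio(seqs: Iterable[BIOSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            for tok, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


# --------------------------------------------------------------------------
# Pair tables (the relaxed-match CSV)
# --------------------------------------------------------------------------

_CORE_COLUMNS = ("doc_id", "surface", "y_true", "y_pred")


def read_pairs(path: str | Path, delimiter: str = ";") -> list[LabelPair]:
    """Load a delimited pair table; ``y_true``/``y_pred`` columns required.

    Extra columns (e.g. ``Compare``) are preserved on each pair's
    ``extra`` mapping and ignored by scoring.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("y_true", "y_pred"):
        if col not in df.columns:
            raise InvariantError(f"{path}: missing required column {col!r}")
    extras = [c for c in df.columns if c not in _CORE_COLUMNS]
    pairs = []
    for d in df.to_dict("records"):
        pairs.append(
            LabelPair(
                doc_id=str(d.get("doc_id", "")),
                surface=str(d.get("surface", "")),
                y_true=d["y_true"],
                y_pred=d["y_pred"],
                extra=tuple((c, str(d[c])) for c in extras),
            )
        )
    return pairs


def pairs_to_frame(pairs: Sequence[LabelPair]) -> pd.DataFrame:
    extras: list[str] = []
    for p in pairs:
        for key, _ in p.extra:
            if key not in extras:
                extras.append(key)
    rows = []
    for p in pairs:
        d = {
            "doc_id": p.doc_id,
            "surface": p.surface,
            "y_true": p.y_true,
            "y_pred": p.y_pred,
        }
        d.update(dict(p.extra))
        rows.append(d)
    return pd.DataFrame(rows, columns=[*_CORE_COLUMNS, *extras])


def write_pairs(
    pairs: Sequence[LabelPair], path: str | Path, delimiter: str = ";"
) -> None:
    pairs_to_frame(pairs).to_csv(path, sep=delimiter, index=False)
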