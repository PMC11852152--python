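"""Inline HTML-span markup codec.

Annotated reports are exchanged as plain text in which each entity is
wrapped in ``<span class="LABEL">…</span>``.  The dialect is deliberately
tiny: one ``class`` attribute holding one entity label, no nesting, no
other markup.  Model responses arrive inside a fenced code block, so an
extractor for triple-backtick fences lives here too.

Parsing is offset-exact: the returned document text is the input with
the span tags removed, and every span indexes that stripped text, so a
parse → render round trip is the identity.  A small hand-written scanner
is used rather than an HTML parser because the contract here is
character-level (verbatim text preservation, per-position structural
errors), which general HTML parsers do not provide.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable

from .core import AnnotatedDocument, InvalidLabelError, LABELS, Span

__all__ = [
    "parse_markup",
    "render_markup",
    "extract_code_block",
    "combine_fragments",
    "split_fragments",
    "MarkupError",
    "MarkupWarning",
]


class MarkupError(ValueError):
    """Structurally invalid span markup (nesting, unclosed or stray tags)."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class MarkupWarning(UserWarning):
    """Recoverable markup irregularities (dropped labels, missing fences)."""


# Typographic quotes appear in attribute values in the wild; normalise
# them (attributes only -- document text is never touched).
_QUOTE = "\"'“”‘’"
_OPEN_TAG = re.compile(
    rf"<span\s+class\s*=\s*[{_QUOTE}]([^{_QUOTE}<>]*)[{_QUOTE}]\s*>",
)
_CLOSE_TAG = re.compile(r"</span\s*>")
_ANY_TAG = re.compile(f"(?:{_OPEN_TAG.pattern})|(?:{_CLOSE_TAG.pattern})")


def parse_markup(
    html_text: str, doc_id: str = "", *, allow_unknown: bool = False
) -> AnnotatedDocument:
    """Parse span-annotated text into an :class:`AnnotatedDocument`.

    Parameters
    ----------
    html_text
        Text containing zero or more flat ``<span class="LABEL">`` elements.
        Both ``class="X"`` and the spaced ``class = "X"`` dialect are
        accepted, with straight or typographic quotes.
    doc_id
        Identifier recorded on the returned document.
    allow_unknown
        When true, spans with a label outside the schema are dropped with
        a :class:`MarkupWarning` instead of raising.

    Raises
    ------
    InvalidLabelError
        Unknown class value (unless ``allow_unknown``).
    MarkupError
        Nested, unclosed, or unmatched span tags, with the character
        position in the input.
    """
    out: list[str] = []
    out_len = 0
    spans: list[Span] = []
    open_label: str | None = None
    open_at = -1  # offset in stripped text
    open_pos = -1  # offset in raw input, for error messages
    pos = 0
    for m in _ANY_TAG.finditer(html_text):
        gap = html_text[pos : m.start()]
        out.append(gap)
        out_len += len(gap)
        pos = m.end()
        label = m.group(1)
        if label is not None:  # opening tag
            if open_label is not None:
                raise MarkupError("nested <span> is not allowed", m.start())
            if label not in LABELS:
                if allow_unknown:
                    warnings.warn(
                        f"{doc_id}: dropping span with unknown label {label!r}",
                        MarkupWarning,
                        stacklevel=2,
                    )
                    open_label = ""  # sentinel: strip tags, record nothing
                else:
                    raise InvalidLabelError(
                        f"{doc_id}: unknown entity label {label!r} in markup"
                    )
            else:
                open_label = label
            open_at = out_len
            open_pos = m.start()
        else:  # closing tag
            if open_label is None:
                raise MarkupError("</span> without matching <span>", m.start())
            if open_label and out_len > open_at:
                spans.append(Span(open_at, out_len, open_label))
            open_label = None
    if open_label is not None:
        raise MarkupError("unclosed <span>", open_pos)
    tail = html_text[pos:]
    out.append(tail)
    return AnnotatedDocument(doc_id, "".join(out), tuple(spans))


def render_markup(doc: AnnotatedDocument) -> str:
    """Render a document back to inline span markup.

    The canonical attribute form ``class="LABEL"`` is emitted, so
    ``parse_markup(render_markup(doc))`` reproduces *doc* exactly.
    """
    parts: list[str] = []
    cursor = 0
    for sp in doc.spans:  # AnnotatedDocument guarantees sorted, disjoint
        parts.append(doc.text[cursor : sp.start])
        parts.append(f'<span class="{sp.label}">{doc.text[sp.start:sp.end]}</span>')
        cursor = sp.end
    parts.append(doc.text[cursor:])
    return "".join(parts)


_FENCE = re.compile(r"```[^\n`]*\n(.*?)```", re.DOTALL)


def extract_code_block(llm_response: str) -> str:
    """Return the interior of the first triple-backtick fence.

    Models are instructed to return the annotated report inside a code
    snippet window; when no fence is present the full response is
    returned and a :class:`MarkupWarning` is emitted.  Multiple fences
    also warn and return the first.
    """
    blocks = _FENCE.findall(llm_response)
    if not blocks:
        warnings.warn(
            "response contains no fenced code block; using full text",
            MarkupWarning,
            stacklevel=2,
        )
        return llm_response
    if len(blocks) > 1:
        warnings.warn(
            f"response contains {len(blocks)} fenced blocks; using the first",
            MarkupWarning,
            stacklevel=2,
        )
    return blocks[0]


_DELIM = re.compile(r"^<!--\s*doc:\s*(.*?)\s*-->\s*?\n", re.MULTILINE)


def combine_fragments(fragments: Iterable[tuple[str, str]]) -> str:
    """Concatenate (doc_id, markup) fragments with comment delimiters."""
    parts = []
    for doc_id, markup in fragments:
        parts.append(f"<!-- doc: {doc_id} -->\n{markup.rstrip()}\n")
    return "\n".join(parts)


def split_fragments(combined: str) -> list[tuple[str, str]]:
    """Inverse of :func:`combine_fragments` (trailing whitespace modulo)."""
    matches = list(_DELIM.finditer(combined))
    out = []
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(combined)
        out.append((m.group(1), combined[m.end() : end].rstrip("\n")))
    return out
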