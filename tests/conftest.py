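"""Shared fixtures: printed reference tables and document strategies.

The relaxed-match confusion matrix and the exact-match TP/FP/FN counts
below are published reference inputs for the evaluation this package
implements; tests rebuild pair multisets and metrics from them.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from promptner import AnnotatedDocument, LabelPair, LABELS, Span

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Relaxed-match confusion matrix of the reference evaluation
# (true label x predicted label), class order sorted.
CONFUSION_LABELS = ("ANAT", "IMP", "O", "OBS-A", "OBS-P", "OBS-U")
CONFUSION_COUNTS = (
    (784, 0, 0, 0, 0, 1),
    (0, 339, 1, 1, 4, 0),
    (11, 0, 1069, 2, 2, 0),
    (0, 0, 0, 366, 0, 0),
    (0, 0, 0, 0, 732, 0),
    (0, 1, 1, 0, 0, 120),
)

# Exact-match per-entity counts (tp, fp, fn) of the reference evaluation.
EXACT_COUNTS = {
    "ANAT": (710, 87, 102),
    "IMP": (307, 75, 83),
    "OBS-A": (206, 16, 9),
    "OBS-P": (719, 191, 206),
    "OBS-U": (91, 18, 21),
}


def pairs_from_matrix(
    labels=CONFUSION_LABELS, counts=CONFUSION_COUNTS
) -> list[LabelPair]:
    """Expand a confusion matrix into the pair multiset it encodes."""
    pairs = []
    for i, t in enumerate(labels):
        for j, p in enumerate(labels):
            pairs.extend(
                LabelPair("ref", f"unit {i} {j} {k}", t, p)
                for k in range(counts[i][j])
            )
    return pairs


@pytest.fixture(scope="session")
def table_pairs() -> list[LabelPair]:
    return pairs_from_matrix()


# ---------------------------------------------------------------------------
# Hypothesis strategies
# ---------------------------------------------------------------------------

_WORDS = (
    "sağ", "sol", "meme", "aksilla", "opasite", "kitle", "dansite", "cilt",
    "breast", "mass", "density", "axilla", "node", "skin", "lesion",
    "İzlenen", "değerlendirildi", "normal", "stable",
)
_PUNCT_WORDS = ("-lezyon", "nodül,", "(benign)", "kitle.", "a-b")


@st.composite
def token_texts(draw, min_words=1, max_words=14, punct=False):
    pool = _WORDS + _PUNCT_WORDS if punct else _WORDS
    words = draw(st.lists(st.sampled_from(pool), min_size=min_words,
                          max_size=max_words))
    return " ".join(words)


@st.composite
def annotated_documents(draw, max_spans=6, token_aligned=True, punct=False):
    """Documents with up to ``max_spans`` disjoint labeled spans.

    With ``token_aligned`` the spans cover whole whitespace words, so
    BIO encoding is well-defined; otherwise spans are arbitrary
    non-empty character ranges.
    """
    text = draw(token_texts(min_words=2, max_words=14, punct=punct))
    n = len(text)
    k = draw(st.integers(0, max_spans))
    spans: list[Span] = []
    if token_aligned:
        bounds = []
        start = None
        for i, ch in enumerate(text + " "):
            if ch != " " and start is None:
                start = i
            elif ch == " " and start is not None:
                bounds.append((start, i))
                start = None
        picked = sorted(draw(st.sets(st.integers(0, len(bounds) - 1), max_size=k)))
        used_until = -1
        for w in picked:
            if bounds[w][0] <= used_until:
                continue
            span_words = draw(st.integers(1, 2))
            last = min(w + span_words - 1, len(bounds) - 1)
            spans.append(
                Span(bounds[w][0], bounds[last][1], draw(st.sampled_from(LABELS)))
            )
            used_until = bounds[last][1]
    else:
        cursor = 0
        for _ in range(k):
            if cursor >= n - 1:
                break
            s = draw(st.integers(cursor, n - 1))
            e = draw(st.integers(s + 1, min(n, s + 8)))
            spans.append(Span(s, e, draw(st.sampled_from(LABELS))))
            cursor = e
    return AnnotatedDocument("hyp", text, tuple(spans))


@st.composite
def document_pairs(draw, max_spans=6):
    """Reference/predicted pairs over identical text, spans independent."""
    ref = draw(annotated_documents(max_spans=max_spans, token_aligned=False))
    text = ref.text
    n = len(text)
    k = draw(st.integers(0, max_spans))
    spans: list[Span] = []
    cursor = 0
    for _ in range(k):
        if cursor >= n - 1:
            break
        s = draw(st.integers(cursor, n - 1))
        e = draw(st.integers(s + 1, min(n, s + 8)))
        spans.append(Span(s, e, draw(st.sampled_from(LABELS))))
        cursor = e
    pred = AnnotatedDocument("hyp-pred", text, tuple(spans))
    return ref, pred
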