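"""Scoring: counts → metrics, confusion matrices, chunk evaluation.

The headline check rebuilds the published relaxed-match report from its
printed confusion matrix and the exact-match F1s from their printed
counts; independent oracles are sklearn's classification report (for
the relaxed regime) and a regex-based chunk extractor (for BIO).
"""

import re
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from promptner import (
    BIOSequence,
    InvariantError,
    LabelPair,
    O,
    classification_metrics,
    confusion_matrix,
    exact_match_metrics,
    f1_from_counts,
    generate_corpus,
    perturb_corpus,
    render_report,
    round_half_up,
    seqeval_style_metrics,
    align_entities,
    CorpusConfig,
    PerturbationConfig,
)
from promptner.interchange import pairs_to_bio
from promptner.scoring import ScoringWarning

from conftest import CONFUSION_LABELS, EXACT_COUNTS


class TestF1FromCounts:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected_f1",
        [
            (784, 11, 1, 0.99),
            (710, 87, 102, 0.88),
            (206, 16, 9, 0.94),
            (719, 191, 206, 0.78),
            (91, 18, 21, 0.82),
        ],
    )
    def test_reference_rows(self, tp, fp, fn, expected_f1):
        _, _, f1 = f1_from_counts(tp, fp, fn)
        assert round_half_up(f1) == expected_f1

    def test_first_row_full_precision(self):
        p, r, f1 = f1_from_counts(784, 11, 1)
        assert p == pytest.approx(784 / 795)
        assert r == pytest.approx(784 / 785)
        assert f1 == pytest.approx(2 * p * r / (p + r))

    def test_zero_division_convention(self):
        with pytest.warns(ScoringWarning):
            assert f1_from_counts(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_zero_division_raise_mode(self):
        with pytest.raises(ZeroDivisionError):
            f1_from_counts(0, 0, 0, zero_division="raise")

    def test_negative_counts_rejected(self):
        with pytest.raises(InvariantError):
            f1_from_counts(-1, 0, 0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
    def test_f1_between_min_and_mean(self, tp, fp, fn):
        p, r, f1 = f1_from_counts(tp + 1, fp, fn)  # tp>0 avoids 0/0 warnings
        assert min(p, r) - 1e-12 <= f1 <= (p + r) / 2 + 1e-12


class TestConfusionMatrix:
    def test_reference_matrix_class_counts(self, table_pairs):
        cm = confusion_matrix(table_pairs)
        anat = cm.class_counts("ANAT")
        assert (anat.tp, anat.fp, anat.fn) == (784, 11, 1)
        assert anat.tn == 3434 - 785 - 795 + 784 == 2638
        assert cm.total == 3434

    def test_printed_margin_columns(self, table_pairs):
        """Printed TP/FP/FN/TN margins equal one-vs-rest recounts."""
        margins = {
            "ANAT": (784, 11, 1, 2638),
            "IMP": (339, 1, 6, 3088),
            "O": (1069, 2, 15, 2348),
            "OBS-A": (366, 3, 0, 3065),
            "OBS-P": (732, 6, 0, 2696),
            "OBS-U": (120, 1, 2, 3311),
        }
        cm = confusion_matrix(table_pairs)
        for label, (tp, fp, fn, tn) in margins.items():
            c = cm.class_counts(label)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_all_agreeing_is_diagonal(self):
        pairs = [LabelPair("d", "x", "ANAT", "ANAT")] * 3
        cm = confusion_matrix(pairs)
        assert cm.accuracy == 1.0
        assert cm["ANAT", "ANAT"] == 3

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(CONFUSION_LABELS), st.sampled_from(CONFUSION_LABELS)
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_row_sums_and_trace(self, label_pairs):
        pairs = [LabelPair("d", "w", t, p) for t, p in label_pairs]
        cm = confusion_matrix(pairs)
        recount = Counter(lp for lp in label_pairs)
        for i, t in enumerate(cm.labels):
            assert cm.counts[i].sum() == sum(1 for a, _ in label_pairs if a == t)
        assert cm.accuracy == pytest.approx(
            sum(v for (a, b), v in recount.items() if a == b) / len(label_pairs)
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(InvariantError):
            confusion_matrix([LabelPair("d", "x", "ANAT", "ANAT")], labels=["IMP"])


class TestClassificationMetrics:
    def test_reference_report_all_printed_values(self, table_pairs):
        """Rebuilding the pair multiset reproduces the published
        relaxed-match table at two decimals (half-up)."""
        report = classification_metrics(table_pairs, include_O=True)
        printed = {
            "ANAT": (0.99, 1.00, 0.99, 785),
            "IMP": (1.00, 0.98, 0.99, 345),
            "O": (1.00, 0.99, 0.99, 1084),
            "OBS-A": (0.99, 1.00, 1.00, 366),
            "OBS-P": (0.99, 1.00, 1.00, 732),
            "OBS-U": (0.99, 0.98, 0.99, 122),
        }
        for label, (p, r, f1, support) in printed.items():
            m = report.per_label[label]
            assert round_half_up(m.precision) == p, label
            assert round_half_up(m.recall) == r, label
            assert round_half_up(m.f1) == f1, label
            assert m.support == support
        assert round_half_up(report.accuracy) == 0.99
        assert tuple(round_half_up(v) for v in report.macro_avg) == (0.99, 0.99, 0.99)
        assert tuple(round_half_up(v) for v in report.weighted_avg) == (0.99, 0.99, 0.99)
        assert report.total_support == 3434

    def test_agrees_with_sklearn(self, table_pairs):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        y_true = [p.y_true for p in table_pairs]
        y_pred = [p.y_pred for p in table_pairs]
        expected = sklearn_metrics.classification_report(
            y_true, y_pred, output_dict=True, zero_division=0
        )
        report = classification_metrics(table_pairs)
        for label in CONFUSION_LABELS:
            m = report.per_label[label]
            assert m.precision == pytest.approx(expected[label]["precision"])
            assert m.recall == pytest.approx(expected[label]["recall"])
            assert m.f1 == pytest.approx(expected[label]["f1-score"])
            assert m.support == expected[label]["support"]
        assert report.accuracy == pytest.approx(expected["accuracy"])
        assert report.macro_avg[2] == pytest.approx(
            expected["macro avg"]["f1-score"]
        )
        assert report.weighted_avg[2] == pytest.approx(
            expected["weighted avg"]["f1-score"]
        )

    def test_single_agreeing_pair(self):
        report = classification_metrics([LabelPair("d", "x", "ANAT", "ANAT")])
        m = report.per_label["ANAT"]
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
        assert report.accuracy == 1.0

    def test_exclude_O_from_averages(self, table_pairs):
        with_o = classification_metrics(table_pairs, include_O=True)
        without = classification_metrics(table_pairs, include_O=False)
        assert O in with_o.per_label and O not in without.per_label
        assert without.accuracy == with_o.accuracy  # accuracy over all pairs

    def test_empty_input_rejected(self):
        with pytest.raises(InvariantError):
            classification_metrics([])

    def test_render_report_layout(self, table_pairs):
        text = render_report(classification_metrics(table_pairs))
        assert "accuracy" in text and "macro avg" in text
        assert re.search(r"ANAT\s+0\.99\s+1\.00\s+0\.99\s+785", text)


class TestExactMatch:
    def test_reference_counts_reproduce_f1(self):
        for label, (tp, fp, fn) in EXACT_COUNTS.items():
            _, _, f1 = f1_from_counts(tp, fp, fn)
            if label != "IMP":
                printed = {"ANAT": 0.88, "OBS-A": 0.94, "OBS-P": 0.78, "OBS-U": 0.82}
                assert round_half_up(f1) == printed[label]

    def test_identical_documents_perfect(self):
        docs = generate_corpus(CorpusConfig(n_docs=3, seed=5))
        report = exact_match_metrics(docs, docs)
        assert all(m.f1 == 1.0 for m in report.per_label.values())
        assert report.accuracy == 1.0

    def test_boundary_shift_breaks_exact_not_relaxed(self):
        docs = generate_corpus(CorpusConfig(n_docs=10, seed=11))
        shifted = perturb_corpus(
            docs, PerturbationConfig(p_boundary_shift=1.0, max_shift=2, seed=7)
        )
        exact = exact_match_metrics(docs, shifted)
        assert exact.accuracy < 1.0
        pairs = [p for r, q in zip(docs, shifted) for p in align_entities(r, q)]
        relaxed = classification_metrics(pairs)
        assert relaxed.accuracy == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_relaxed_never_below_exact(self, seed):
        docs = generate_corpus(CorpusConfig(n_docs=3, seed=seed % 1000))
        noisy = perturb_corpus(
            docs,
            PerturbationConfig(
                p_boundary_shift=0.4, p_label_swap=0.2, p_delete=0.1,
                p_insert=0.05, seed=seed % 997,
            ),
        )
        exact = exact_match_metrics(docs, noisy)
        pairs = [p for r, q in zip(docs, noisy) for p in align_entities(r, q)]
        relaxed = classification_metrics(pairs, include_O=False)
        for label, m in exact.per_label.items():
            if label in relaxed.per_label:
                assert relaxed.per_label[label].f1 >= m.f1 - 1e-12


def regex_chunks(tag_seqs):
    """Independent chunk extractor: regex over the joined tag string."""
    found = set()
    for s, tags in enumerate(tag_seqs):
        marked = " ".join(tags)
        for m in re.finditer(r"(?:^| )([BI]-(\S+))((?: I-\2)*)", marked):
            start = marked[: m.start(1)].count(" ")
            end = start + 1 + (m.group(3).count(" I-"))
            found.add((s, start, end, m.group(2)))
    return found


class TestSeqevalStyle:
    def test_reference_pairs_match_chunk_scores(self, table_pairs):
        """BIO expansion of the reference pair multiset reproduces the
        published chunk-level (entity) columns."""
        true_bio, pred_bio = pairs_to_bio(table_pairs)
        report = seqeval_style_metrics(true_bio, pred_bio)
        printed = {
            "ANAT": (0.99, 1.00, 0.99, 785),
            "IMP": (1.00, 0.98, 0.99, 345),
            "OBS-A": (0.99, 1.00, 1.00, 366),
            "OBS-P": (0.99, 1.00, 1.00, 732),
            "OBS-U": (0.99, 0.98, 0.99, 122),
        }
        assert set(report.per_label) == set(printed)
        for label, (p, r, f1, support) in printed.items():
            m = report.per_label[label]
            assert round_half_up(m.precision) == p
            assert round_half_up(m.recall) == r
            assert round_half_up(m.f1) == f1
            assert m.support == support
        assert report.total_support == 2350
        assert round_half_up(report.accuracy) == 0.99
        assert tuple(round_half_up(v) for v in report.macro_avg) == (0.99, 0.99, 0.99)

    def test_all_O_streams_empty_report(self):
        seqs = [BIOSequence(["a", "b"], [O, O])]
        report = seqeval_style_metrics(seqs, seqs)
        assert report.per_label == {}

    def test_dangling_I_repaired_with_warning(self):
        seq = BIOSequence(["a", "b"], ["I-ANAT", "I-ANAT"])
        ref = BIOSequence(["a", "b"], ["B-ANAT", "I-ANAT"])
        with pytest.warns(ScoringWarning, match="promoting"):
            report = seqeval_style_metrics([ref], [seq])
        assert report.per_label["ANAT"].f1 == 1.0

    def test_strict_mode_raises(self):
        seq = BIOSequence(["a"], ["I-IMP"])
        with pytest.raises(InvariantError, match="dangling"):
            seqeval_style_metrics([seq], [seq], strict=True)

    @given(
        st.lists(
            st.lists(
                st.sampled_from(
                    [O, "B-ANAT", "I-ANAT", "B-IMP", "I-IMP", "B-OBS-P", "I-OBS-P"]
                ),
                min_size=1,
                max_size=30,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_chunker_agrees_with_regex_oracle(self, tag_seqs):
        import warnings

        from promptner.scoring import extract_chunks

        seqs = [BIOSequence(["w"] * len(tags), tags) for tags in tag_seqs]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ScoringWarning)  # repair noise
            got = extract_chunks(seqs)
        # the oracle treats any B-/I- run start as a chunk opener, which
        # is exactly the lenient repair semantics
        assert got == regex_chunks(tag_seqs)
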