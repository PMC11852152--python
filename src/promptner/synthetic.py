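"""Synthetic annotated mammography-style reports and error injection.

No real clinical corpus ships with this package, so evaluation code is
exercised on generated reports: short sectioned documents (technique
line, findings sentences, impression line) whose entity phrases are
slot-filled from small phrase pools.  Both an English and a
Turkish-like template set are provided; the method itself is
language-agnostic.

Entity class frequencies default to the profile of the evaluation
corpus this tooling targets (supports ANAT 785, IMP 345, OBS-P 732,
OBS-A 366, OBS-U 122), and the default corpus size is 85 documents —
the size of that test set.  Labels are drawn i.i.d. from the weight
vector, so empirical frequencies are multinomial around the configured
proportions.

The perturbation model turns a reference document into a simulated
prediction with controlled error rates: per-span boundary shifts
(overlap with the original always preserved), label swaps (uniform over
the other classes), deletions, and spurious single-token insertions
over unannotated text.  All randomness flows through one seeded
generator with a fixed draw order (per span: delete, swap, swap-target,
start-shift, end-shift; then one draw per candidate insertion token,
then its label), so runs replay exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import LABELS, AnnotatedDocument, InvariantError, Span
from .interchange import tokenize
from .markup import render_markup
from .prompting import (
    DEFAULT_TRANSITION,
    PromptSpec,
    Shot,
    default_prompt_spec,
    estimate_tokens,
    extract_target,
)

__all__ = [
    "DEFAULT_LABEL_WEIGHTS",
    "CorpusConfig",
    "PerturbationConfig",
    "generate_corpus",
    "perturb",
    "perturb_corpus",
    "PerturbingBackend",
    "emit_replay_fixtures",
    "study_scale_prompt",
]

#: Entity-frequency profile of the target evaluation corpus.
DEFAULT_LABEL_WEIGHTS: dict[str, float] = {
    "ANAT": 785,
    "IMP": 345,
    "OBS-P": 732,
    "OBS-A": 366,
    "OBS-U": 122,
}

_POOLS = {
    "en": {
        "ANAT": (
            "right breast", "left breast", "both breasts",
            "upper outer quadrant", "lower inner quadrant", "left axilla",
            "right axilla", "skin", "nipple-areolar complex",
            "retroareolar region",
        ),
        "OBS-P": (
            "nodular opacity", "benign calcifications",
            "fibroglandular densities", "well-circumscribed mass",
            "ductal ectasia", "coarse calcification",
        ),
        "OBS-A": (
            "spiculated mass", "suspicious microcalcifications",
            "architectural distortion", "skin thickening",
            "pathologic lymph nodes",
        ),
        "OBS-U": (
            "asymmetric density", "focal asymmetry", "summation artifact",
            "equivocal distortion",
        ),
        "IMP": (
            "benign findings, routine screening recommended",
            "probably benign finding, short-interval follow-up advised",
            "negative screening mammogram",
            "stable known findings, annual follow-up",
        ),
    },
    "tr": {
        "ANAT": (
            "sağ meme", "sol meme", "her iki meme", "üst dış kadran",
            "alt iç kadran", "sol aksilla", "sağ aksilla", "cilt",
            "retroareolar bölge",
        ),
        "OBS-P": (
            "nodüler opasite", "benign kalsifikasyonlar",
            "fibroglandüler dansiteler", "düzgün sınırlı kitle",
        ),
        "OBS-A": (
            "spiküle kitle", "şüpheli mikrokalsifikasyon",
            "yapısal distorsiyon", "cilt kalınlaşması",
        ),
        "OBS-U": (
            "asimetrik dansite", "fokal asimetri", "süperpozisyon artefaktı",
        ),
        "IMP": (
            "benign bulgular, rutin tarama önerilir",
            "olasılıkla benign bulgu, kısa aralıklı takip önerilir",
            "negatif tarama mamografisi",
        ),
    },
}

_HEADERS = {
    "en": "Bilateral digital mammography was performed and compared with prior examinations.",
    "tr": "Her iki memenin dijital mamografi görüntüleri önceki tetkiklerle karşılaştırılmıştır.",
}

# Carrier sentences: {0} = first entity phrase, {1} = optional second.
_CARRIERS = {
    "en": {
        "pair-OBS-P": ("A {1} is noted in the {0}.", True),
        "pair-OBS-A": ("No {1} is identified in the {0}.", True),
        "pair-OBS-U": ("Possible {1} in the {0} cannot be excluded.", True),
        "lone-ANAT": ("The {0} is unremarkable.", False),
        "lone-OBS-P": ("There is {0}.", False),
        "lone-OBS-A": ("No {0} is seen.", False),
        "lone-OBS-U": ("Findings may represent {0}.", False),
        "IMP": ("Impression: {0}.", False),
    },
    "tr": {
        "pair-OBS-P": ("{0} içinde {1} izlenmektedir.", True),
        "pair-OBS-A": ("{0} içinde {1} izlenmemiştir.", True),
        "pair-OBS-U": ("{0} içinde {1} ekarte edilememektedir.", True),
        "lone-ANAT": ("{0} olağan görünümdedir.", False),
        "lone-OBS-P": ("{0} mevcuttur.", False),
        "lone-OBS-A": ("{0} saptanmamıştır.", False),
        "lone-OBS-U": ("{0} söz konusu olabilir.", False),
        "IMP": ("Sonuç: {0}.", False),
    },
}


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus generation parameters.

    ``label_weights`` are relative frequencies per entity class;
    ``span_length_range`` restricts entity phrases to that token-count
    range; ``n_entities_range`` is the (inclusive) per-document entity
    count range.  The same seed always yields the identical corpus.
    """

    n_docs: int = 85
    label_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_WEIGHTS)
    )
    span_length_range: tuple[int, int] = (1, 8)
    n_entities_range: tuple[int, int] = (8, 16)
    template_set: str = "en"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise InvariantError("n_docs must be >= 1")
        if self.template_set not in _POOLS:
            raise InvariantError(f"unknown template_set {self.template_set!r}")
        if any(w <= 0 for w in self.label_weights.values()):
            raise InvariantError("label weights must be positive")
        unknown = set(self.label_weights) - set(LABELS)
        if unknown:
            raise InvariantError(f"unknown labels in weights: {sorted(unknown)}")


@dataclass(frozen=True)
class PerturbationConfig:
    """Prediction error model.

    Per span: deleted with ``p_delete``; else label swapped with
    ``p_label_swap``; else/also boundaries shifted with
    ``p_boundary_shift`` by up to ``max_shift`` characters on each side
    (clamped so the span keeps at least one character of overlap with
    the original and never touches a neighbouring span).  Spurious
    single-token spans are inserted over unannotated text at
    ``p_insert`` per document token.
    """

    p_boundary_shift: float = 0.0
    p_label_swap: float = 0.0
    p_delete: float = 0.0
    p_insert: float = 0.0
    max_shift: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_boundary_shift", "p_label_swap", "p_delete", "p_insert"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvariantError(f"{name} must be in [0, 1], got {p}")
        if self.max_shift < 1:
            raise InvariantError("max_shift must be >= 1")


def _weighted_label(rng: np.random.Generator, labels: Sequence[str],
                    cum: np.ndarray) -> str:
    return labels[int(np.searchsorted(cum, rng.random(), side="right"))]


def _pool(config: CorpusConfig, label: str) -> tuple[str, ...]:
    lo, hi = config.span_length_range
    pool = tuple(
        p for p in _POOLS[config.template_set][label] if lo <= len(p.split()) <= hi
    )
    if not pool:
        raise InvariantError(
            f"span_length_range {config.span_length_range} empties the "
            f"{label} phrase pool"
        )
    return pool


def _build_doc(doc_id: str, labels: list[str], config: CorpusConfig,
               rng: np.random.Generator) -> AnnotatedDocument:
    carriers = _CARRIERS[config.template_set]
    parts: list[str] = [_HEADERS[config.template_set]]
    spans: list[Span] = []
    offset = len(parts[0]) + 1  # newline-joined

    def pick(label: str) -> str:
        pool = _pool(config, label)
        return pool[int(rng.integers(len(pool)))]

    queue = list(labels)
    while queue:
        label = queue.pop(0)
        if label == "IMP":
            template, paired = carriers["IMP"]
            fills = [("IMP", pick("IMP"))]
        elif label == "ANAT" and queue and queue[0].startswith("OBS-"):
            obs = queue.pop(0)
            template, paired = carriers[f"pair-{obs}"]
            fills = [("ANAT", pick("ANAT")), (obs, pick(obs))]
        else:
            template, paired = carriers[f"lone-{label}"]
            fills = [(label, pick(label))]
        sentence, sent_spans = _fill(template, fills, offset)
        parts.append(sentence)
        spans.extend(sent_spans)
        offset += len(sentence) + 1
    text = "\n".join(parts)
    return AnnotatedDocument(doc_id, text, tuple(sorted(spans)))


def _fill(template: str, fills: list[tuple[str, str]],
          offset: int) -> tuple[str, list[Span]]:
    # slots may appear in any order in the template ("No {1} … the {0}.")
    slots = sorted(
        (template.index("{" + str(k) + "}"), k) for k in range(len(fills))
    )
    sentence = ""
    spans: list[Span] = []
    cursor = 0
    for at, k in slots:
        label, phrase = fills[k]
        sentence += template[cursor:at]
        start = offset + len(sentence)
        sentence += phrase
        spans.append(Span(start, start + len(phrase), label))
        cursor = at + len("{" + str(k) + "}")
    sentence += template[cursor:]
    return sentence, sorted(spans)


def generate_corpus(config: CorpusConfig = CorpusConfig()) -> list[AnnotatedDocument]:
    """Generate a corpus of annotated reports per the configuration."""
    rng = np.random.default_rng(config.seed)
    labels = tuple(lab for lab in LABELS if lab in config.label_weights)
    weights = np.array([config.label_weights[lab] for lab in labels], dtype=float)
    cum = np.cumsum(weights / weights.sum())
    lo, hi = config.n_entities_range
    docs = []
    for d in range(config.n_docs):
        n_ent = int(rng.integers(lo, hi + 1))
        drawn = [_weighted_label(rng, labels, cum) for _ in range(n_ent)]
        docs.append(_build_doc(f"doc-{d:04d}", drawn, config, rng))
    return docs


def perturb(
    doc: AnnotatedDocument,
    config: PerturbationConfig,
    rng: np.random.Generator | None = None,
) -> AnnotatedDocument:
    """Simulate a model prediction for *doc* under the error model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[Span] = []
    n = len(doc.text)
    for i, sp in enumerate(doc.spans):
        u_delete = rng.random()
        u_swap = rng.random()
        swap_idx = int(rng.integers(len(LABELS) - 1))
        u_shift = rng.random()
        ds = int(rng.integers(-config.max_shift, config.max_shift + 1))
        de = int(rng.integers(-config.max_shift, config.max_shift + 1))
        if u_delete < config.p_delete:
            continue
        label = sp.label
        if u_swap < config.p_label_swap:
            label = [lab for lab in LABELS if lab != label][swap_idx]
        start, end = sp.start, sp.end
        if u_shift < config.p_boundary_shift:
            prev_end = doc.spans[i - 1].end if i > 0 else 0
            next_start = doc.spans[i + 1].start if i + 1 < len(doc.spans) else n
            start = min(max(sp.start + ds, prev_end), sp.end - 1)
            end = max(min(sp.end + de, next_start), sp.start + 1)
            end = max(end, start + 1)
        out.append(Span(start, end, label))

    insert_prob = config.p_insert
    if insert_prob > 0:
        blocked = list(doc.spans) + out
        for tok in tokenize(doc.text):
            u_ins = rng.random()
            ins_label = LABELS[int(rng.integers(len(LABELS)))]
            if u_ins >= insert_prob:
                continue
            cand = Span(tok.start, tok.end, ins_label)
            if all(cand.overlap(b) == 0 for b in blocked):
                out.append(cand)
                blocked.append(cand)
    return doc.with_spans(out)


def perturb_corpus(
    docs: Sequence[AnnotatedDocument], config: PerturbationConfig
) -> list[AnnotatedDocument]:
    """Perturb a whole corpus with one shared seeded generator."""
    rng = np.random.default_rng(config.seed)
    return [perturb(doc, config, rng=rng) for doc in docs]


class PerturbingBackend:
    """Mock annotation backend with configured error rates.

    Looks up the target report (extracted from the prompt) among the
    reference documents, perturbs its annotations, and returns the
    markup inside a code fence — exactly what a flawed but cooperative
    model would produce.
    """

    def __init__(
        self,
        reference_docs: Sequence[AnnotatedDocument],
        config: PerturbationConfig,
        transition: str = DEFAULT_TRANSITION,
        control_phrases: Sequence[str] = (),
    ):
        self._by_text = {doc.text.strip("\n"): doc for doc in reference_docs}
        self._config = config
        self._rng = np.random.default_rng(config.seed)
        self._transition = transition
        self._control = tuple(control_phrases)

    def __call__(self, prompt: str) -> str:
        target = extract_target(prompt, self._transition, self._control)
        doc = self._by_text.get(target.strip("\n"))
        if doc is None:
            raise KeyError("target report not among the reference documents")
        predicted = perturb(doc, self._config, rng=self._rng)
        return f"```\n{render_markup(predicted)}\n```"


def emit_replay_fixtures(
    reference_docs: Sequence[AnnotatedDocument],
    predicted_docs: Sequence[AnnotatedDocument],
    out_dir: str | Path,
) -> None:
    """Write a replay-backend fixture directory for paired documents."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ref, pred in zip(reference_docs, predicted_docs, strict=True):
        (out / f"{ref.doc_id}.input.txt").write_text(ref.text + "\n", encoding="utf-8")
        (out / f"{ref.doc_id}.response.txt").write_text(
            f"```\n{render_markup(pred)}\n```\n", encoding="utf-8"
        )


# --------------------------------------------------------------------------
# Study-scale prompt
# --------------------------------------------------------------------------

_INSTRUCTION_TOKENS = 12278  # component sizes of the targeted prompt design
_N_SHOTS = 165


def study_scale_prompt(
    seed: int = 0, template_set: str = "en"
) -> tuple[PromptSpec, AnnotatedDocument]:
    """Assemble a prompt at the full many-shot design scale.

    The packaged defaults are miniature; this builds the design-sized
    composition — instruction text of ~12,278 tokens, 165 shots, and a
    target report of ~265 tokens — from generated content, for budget
    arithmetic and end-to-end rehearsal.  Returns the prompt components
    together with the reference annotation of the target report.
    """
    spec = default_prompt_spec("placeholder")
    base = spec.instructions

    shot_config = CorpusConfig(
        n_docs=_N_SHOTS, n_entities_range=(1, 3), template_set=template_set,
        seed=seed,
    )
    shots = []
    for doc in generate_corpus(shot_config):
        # shots are example sentences, not whole reports: drop the header
        cut = doc.text.index("\n") + 1
        body = doc.text[cut:]
        spans = tuple(sp.shift(-cut) for sp in doc.spans)
        shot_doc = AnnotatedDocument(doc.doc_id, body, spans)
        shots.append(Shot(body, render_markup(shot_doc)))
    shots = tuple(shots)

    rng = np.random.default_rng(seed + 1)
    lines = [base.rstrip(), "", "Additional annotation guidance:"]
    pools = _POOLS[template_set]
    k = 1
    while estimate_tokens("\n".join(lines)) < _INSTRUCTION_TOKENS:
        label = LABELS[int(rng.integers(len(LABELS)))]
        pool = pools[label]
        phrase = pool[int(rng.integers(len(pool)))]
        lines.append(
            f"{k}. A phrase such as \"{phrase}\" is annotated with the "
            f"{label} class; annotate the minimal phrase and nothing else."
        )
        k += 1
    instructions = "\n".join(lines)

    target_docs = generate_corpus(
        CorpusConfig(
            n_docs=1,
            n_entities_range=(24, 30),
            template_set=template_set,
            seed=seed + 2,
        )
    )
    target = target_docs[0]

    full = PromptSpec(
        instructions=instructions,
        shots=shots,
        target_report=target.text,
        transitional_phrase=DEFAULT_TRANSITION,
        control_phrases=spec.control_phrases,
    )
    return full, target
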