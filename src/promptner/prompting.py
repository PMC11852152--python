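"""Many-shot prompt assembly, annotation backends, and rule-based fixes.

A prompt is an ordered concatenation of five components — instructions,
worked input→output examples ("shots"), a transitional phrase, the
target report, and trailing control phrases that force code-snippet
output.  Assembly is deterministic: an identical
:class:`PromptSpec` always yields a byte-identical prompt, so runs are
reproducible from their components alone.

Backends are plain synchronous ``text → text`` callables; the package
ships offline ones (replay fixtures, an identity echo) so the full loop
is testable without any LLM service.  Live API adapters satisfy the
same contract and live outside the test surface.
"""

from __future__ import annotations

import json
import math
import random
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .core import InvariantError
from .markup import extract_code_block, parse_markup

__all__ = [
    "Shot",
    "PromptSpec",
    "CorrectionRule",
    "DEFAULT_CORRECTION_RULES",
    "DEFAULT_TRANSITION",
    "build_prompt",
    "shuffle_shots",
    "estimate_tokens",
    "annotate_report",
    "apply_corrections",
    "normalize_quotes",
    "default_prompt_spec",
    "spec_from_config",
    "load_shots",
    "load_correction_rules",
    "extract_target",
    "ReplayBackend",
    "IdentityBackend",
    "BudgetError",
    "TransportError",
    "PromptWarning",
]

Backend = Callable[[str], str]
Tokenizer = Callable[[str], int]


class PromptWarning(UserWarning):
    """Recoverable prompt/response irregularities (divergent output, …)."""


class BudgetError(ValueError):
    """Assembled prompt exceeds the configured token budget."""

    def __init__(self, estimate: int, budget: int):
        super().__init__(
            f"prompt estimate {estimate} tokens exceeds budget {budget} "
            f"(overflow {estimate - budget})"
        )
        self.estimate = estimate
        self.budget = budget


class TransportError(RuntimeError):
    """Backend failed after the configured number of retries."""

    def __init__(self, attempts: int, cause: Exception):
        super().__init__(f"backend failed after {attempts} attempt(s): {cause}")
        self.attempts = attempts


_QUOTE_MAP = str.maketrans({"“": '"', "”": '"', "‘": "'", "’": "'"})


def normalize_quotes(text: str) -> str:
    """Map typographic (curly) quotes to their straight equivalents."""
    return text.translate(_QUOTE_MAP)


@dataclass(frozen=True)
class Shot:
    """One worked example: a raw sentence and its annotated form."""

    input_text: str
    output_markup: str

    def validate(self) -> None:
        """Check that the markup strips back to the input text."""
        stripped = parse_markup(self.output_markup).text
        if " ".join(stripped.split()) != " ".join(self.input_text.split()):
            raise InvariantError(
                f"shot output does not strip to its input: {self.input_text!r}"
            )


@dataclass
class PromptSpec:
    """Ordered prompt components.

    The assembled order is fixed: instructions → shots → transitional
    phrase → target report → control phrases.  ``token_estimate`` is
    populated by :func:`build_prompt`.
    """

    instructions: str
    shots: Sequence[Shot]
    target_report: str
    transitional_phrase: str = ""
    control_phrases: Sequence[str] = ()
    token_estimate: int = 0

    def __post_init__(self) -> None:
        self.shots = tuple(self.shots)
        self.control_phrases = tuple(self.control_phrases)


DEFAULT_TRANSITION = "Here is the mammography report to be tagged:"


def shuffle_shots(shots: Sequence[Shot], seed: int) -> tuple[Shot, ...]:
    """Seeded reordering of a shot list, for shot-order ablations.

    Shots are otherwise always kept in authored order; this is the only
    sanctioned way to vary it, so the permutation is reproducible.
    """
    order = list(shots)
    random.Random(seed).shuffle(order)
    return tuple(order)


def estimate_tokens(text: str, tokenizer: Tokenizer | None = None) -> int:
    """Token count of *text*.

    The default heuristic is ``ceil(code_points / 4)`` — the common
    rule of thumb for subword tokenizers on Latin-script text.  Pass a
    ``tokenizer`` callable for an exact count.
    """
    if tokenizer is not None:
        return tokenizer(text)
    return math.ceil(len(text) / 4)


def _render_shot(i: int, shot: Shot) -> str:
    return f"Example {i}:\nInput: {shot.input_text}\nOutput: {shot.output_markup}"


def build_prompt(
    spec: PromptSpec,
    *,
    budget: int | None = None,
    tokenizer: Tokenizer | None = None,
) -> str:
    """Assemble the prompt text and populate ``spec.token_estimate``.

    Components are concatenated in the invariant order with blank-line
    separators.  When ``budget`` is given and the estimate exceeds it,
    a :class:`BudgetError` reports the overflow.
    """
    if not spec.instructions or not spec.target_report:
        raise InvariantError("instructions and target_report must be non-empty")
    transition = spec.transitional_phrase or DEFAULT_TRANSITION
    parts = [spec.instructions.rstrip()]
    parts.extend(_render_shot(i + 1, s) for i, s in enumerate(spec.shots))
    parts.append(f"{transition}\n{spec.target_report.rstrip()}")
    parts.extend(p.rstrip() for p in spec.control_phrases)
    prompt = "\n\n".join(parts) + "\n"
    spec.token_estimate = estimate_tokens(prompt, tokenizer)
    if budget is not None and spec.token_estimate > budget:
        raise BudgetError(spec.token_estimate, budget)
    return prompt


def extract_target(
    prompt: str,
    transition: str = DEFAULT_TRANSITION,
    control_phrases: Sequence[str] = (),
) -> str:
    """Recover the target report from an assembled prompt."""
    idx = prompt.rfind(transition)
    if idx < 0:
        raise InvariantError("prompt contains no transitional phrase")
    tail = prompt[idx + len(transition) :]
    for phrase in control_phrases:
        cut = tail.find(phrase)
        if cut >= 0:
            tail = tail[:cut]
    return tail.strip("\n")


# --------------------------------------------------------------------------
# Backends
# --------------------------------------------------------------------------

class ReplayBackend:
    """Offline backend replaying stored responses.

    Keyed by target text: the stored input whose text occurs in the
    prompt selects the stored response.  Fixture directories hold
    ``<doc_id>.input.txt`` / ``<doc_id>.response.txt`` file pairs.
    """

    def __init__(self, responses: Mapping[str, str]):
        self._responses = dict(responses)

    @classmethod
    def from_dir(cls, fixture_dir: str | Path) -> "ReplayBackend":
        fixture_dir = Path(fixture_dir)
        responses = {}
        for inp in sorted(fixture_dir.glob("*.input.txt")):
            doc_id = inp.name[: -len(".input.txt")]
            resp = fixture_dir / f"{doc_id}.response.txt"
            responses[inp.read_text(encoding="utf-8").strip("\n")] = resp.read_text(
                encoding="utf-8"
            )
        return cls(responses)

    def __call__(self, prompt: str) -> str:
        for target, response in self._responses.items():
            if target and target in prompt:
                return response
        raise KeyError("no stored response matches the prompt's target report")


class IdentityBackend:
    """Echoes the target report unannotated, inside a code fence."""

    def __init__(self, transition: str = DEFAULT_TRANSITION,
                 control_phrases: Sequence[str] = ()):
        self.transition = transition
        self.control_phrases = tuple(control_phrases)

    def __call__(self, prompt: str) -> str:
        target = extract_target(prompt, self.transition, self.control_phrases)
        return f"```\n{target}\n```"


def annotate_report(
    prompt: str,
    backend: Backend,
    *,
    retries: int = 2,
    target_text: str | None = None,
) -> str:
    """Dispatch a prompt to a backend and return the annotated markup.

    The response passes through :func:`extract_code_block`.  Backend
    exceptions are retried up to ``retries`` extra times, then wrapped
    in :class:`TransportError`.  If ``target_text`` is given and the
    markup strips to a different text, a divergence warning is emitted.
    """
    attempts = 0
    while True:
        attempts += 1
        try:
            response = backend(prompt)
            break
        except Exception as err:  # noqa: BLE001 - backend contract is opaque
            if attempts > retries:
                raise TransportError(attempts, err) from err
    markup = extract_code_block(response).strip("\n")
    if target_text is not None:
        stripped = parse_markup(markup, allow_unknown=True).text
        if " ".join(stripped.split()) != " ".join(target_text.split()):
            warnings.warn(
                "annotated response strips to a different text than the target",
                PromptWarning,
                stacklevel=2,
            )
    return markup


# --------------------------------------------------------------------------
# Rule-based corrections
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionRule:
    """Literal replacement fixing a recurrent mis-annotation."""

    wrong: str
    corrected: str

    def __post_init__(self) -> None:
        if not self.wrong:
            raise InvariantError("correction rule 'wrong' string must be non-empty")
        if self.wrong == self.corrected:
            raise InvariantError("correction rule must change the text")


# Recurrent boilerplate mis-annotations observed on Turkish mammography
# reports: technique/comparison sentences that must stay unannotated.
DEFAULT_CORRECTION_RULES: tuple[CorrectionRule, ...] = tuple(
    CorrectionRule(wrong, corrected)
    for wrong, corrected in [
        (
            '<span class = "ANAT">Sol memenin</span> MLO ve CC mammogramları elde olunmuştur',
            "Sol memenin MLO ve CC mammogramları elde olunmuştur",
        ),
        (
            '<span class = "ANAT">Sağ memenin</span> MLO ve CC mammogramları elde olunmuştur',
            "Sağ memenin MLO ve CC mammogramları elde olunmuştur",
        ),
        (
            '<span class = "ANAT">SAĞ</span> MAMMOGRAFİ RAPORUNUN DA OKUNMASI ÖNERİLİR',
            "SAĞ MAMMOGRAFİ RAPORUNUN DA OKUNMASI ÖNERİLİR",
        ),
        (
            '<span class = "ANAT">SOL</span> MAMMOGRAFİ RAPORUNUN DA OKUNMASI ÖNERİLİR',
            "SOL MAMMOGRAFİ RAPORUNUN DA OKUNMASI ÖNERİLİR",
        ),
    ]
)


def apply_corrections(
    markup: str, rules: Sequence[CorrectionRule] = DEFAULT_CORRECTION_RULES
) -> str:
    """Apply literal substring corrections in order.

    Each rule is matched both verbatim and with typographic quotes
    normalised to straight ones (models emit either dialect in the span
    attributes), so the rest of the text is never rewritten.  The
    operation is idempotent: corrected strings match no rule.
    """
    for rule in rules:
        variants = {rule.wrong, normalize_quotes(rule.wrong)}
        # also match the curly-attribute rendering of a straight-quoted rule
        variants.add(rule.wrong.replace(' = "', " = “").replace('">', "”>"))
        for wrong in variants:
            if wrong != rule.corrected:
                markup = markup.replace(wrong, rule.corrected)
    return markup


def load_correction_rules(path: str | Path) -> tuple[CorrectionRule, ...]:
    """Load user rules (JSON list of {wrong, corrected}) appended after defaults."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    user = tuple(CorrectionRule(d["wrong"], d["corrected"]) for d in data)
    return DEFAULT_CORRECTION_RULES + user


# --------------------------------------------------------------------------
# Packaged default components
# --------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return (
        resources.files("promptner").joinpath("data/prompts").joinpath(name)
    ).read_text(encoding="utf-8")


def load_shots(source: str | Path | Iterable[str]) -> tuple[Shot, ...]:
    """Read shots from a JSONL source with ``input``/``output`` keys."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source
    shots = []
    for line in lines:
        if line.strip():
            rec = json.loads(line)
            shots.append(Shot(rec["input"], rec["output"]))
    return tuple(shots)


def spec_from_config(
    config_path: str | Path, target_report: str
) -> tuple[PromptSpec, int | None, tuple[CorrectionRule, ...]]:
    """Build a prompt spec from a key-value config file.

    Recognised keys (one ``key = value`` per line, ``#`` comments):
    ``instructions``, ``shots``, ``transition``, ``control`` (component
    file paths, relative to the config file), ``rules`` (correction
    rules JSON appended after the defaults) and ``budget`` (token
    budget, integer).  Unset components fall back to the packaged
    defaults.  Returns (spec, budget, correction rules).
    """
    config_path = Path(config_path)
    base = config_path.parent
    entries: dict[str, str] = {}
    for line in config_path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    unknown = set(entries) - {
        "instructions", "shots", "transition", "control", "rules", "budget"
    }
    if unknown:
        raise InvariantError(f"unknown prompt config keys: {sorted(unknown)}")

    def _component(key: str, fallback: str) -> str:
        if key in entries:
            return (base / entries[key]).read_text(encoding="utf-8")
        return fallback

    spec = PromptSpec(
        instructions=_component("instructions", _data_text("instructions.txt")),
        shots=load_shots((base / entries["shots"]))
        if "shots" in entries
        else load_shots(_data_text("shots.jsonl").splitlines()),
        target_report=target_report,
        transitional_phrase=_component(
            "transition", DEFAULT_TRANSITION
        ).strip("\n"),
        control_phrases=tuple(
            line
            for line in _component("control", _data_text("control.txt")).splitlines()
            if line.strip()
        ),
    )
    budget = int(entries["budget"]) if "budget" in entries else None
    rules = (
        load_correction_rules(base / entries["rules"])
        if "rules" in entries
        else DEFAULT_CORRECTION_RULES
    )
    return spec, budget, rules


def default_prompt_spec(target_report: str) -> PromptSpec:
    """Prompt spec from the packaged miniature English components.

    These defaults demonstrate the prompt structure at desk scale; a
    production run replaces them with a domain-scale instruction text
    and shot library via the same loaders.
    """
    return PromptSpec(
        instructions=_data_text("instructions.txt"),
        shots=load_shots(_data_text("shots.jsonl").splitlines()),
        target_report=target_report,
        transitional_phrase=DEFAULT_TRANSITION,
        control_phrases=tuple(
            line for line in _data_text("control.txt").splitlines() if line.strip()
        ),
    )
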