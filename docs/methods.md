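# Methods

This note records the models, conventions and numerical choices behind
`promptner`, in the order data flows through the pipeline.

## Annotation schema and markup dialect

A document is plain text plus a flat list of labeled character spans:
sorted, non-overlapping, never nested. Offsets are 0-based, half-open,
and counted in Unicode code points; no case folding is ever applied,
so Turkish dotted/dotless *i* distinctions survive every conversion.
Five classes are allowed on spans (`ANAT`, `IMP`, `OBS-P`, `OBS-A`,
`OBS-U`); `O` marks non-entity units in evaluation rows and BIO tags
and is never a span label.

The markup dialect is a single `<span>` element with one `class`
attribute. Both the spaced (`class = "ANAT"`) and unspaced attribute
forms are accepted, with straight or typographic quotes — source
material and model output mix these freely — and rendering always
emits the canonical unspaced straight-quoted form, which makes
parse∘render the identity. Nested spans are a structural error, not
silently flattened: the schema is flat, and flattening would corrupt
offsets downstream. Unknown labels fail hard by default; an
`allow_unknown` escape hatch drops them with a warning for salvaging
malformed model output. The parser is a small scanner rather than an
HTML-parser wrapper because the contract is character-level (verbatim
text preservation, per-position structural errors), which DOM parsers
do not expose.

Model responses are expected inside a triple-backtick fence (the
control phrases in the prompt enforce this); the extractor accepts any
fence with or without a language word, returns the first block when
several appear, and falls back to the whole response with a warning
when none does.

## Tokenization and punctuation detachment

The default tokenizer splits on whitespace and then detaches leading
and trailing punctuation (Unicode category P) as standalone
single-character tokens, so `atelectasis -infarction` yields three
tokens. This reproduces the punctuation sensitivity that tokenized
exact-match evaluation imposes without pulling in a language-specific
model — morphological tokenization of Turkish is deliberately out of
scope. `detach_punctuation` additionally inserts a space wherever an
entity boundary butts against punctuation with no intervening
whitespace; it is required only upstream of tokenized exact-match
scoring, never for relaxed alignment, and preserves every span surface
modulo the inserted whitespace.

## Alignment (relaxed matching)

Given a reference and a predicted document over identical text, spans
are matched one-to-one, requiring at least `overlap_rule` shared
characters (default 1). The matcher maximises **total character
overlap exactly**. A greedy longest-overlap-first heuristic was
considered and rejected: it is not optimal (reference spans [0,10) and
[11,20) against predictions [0,4) and [5,14) make greedy take the
single overlap-5 pair where the optimum is 4+3), and an evaluation
primitive should not depend on heuristic luck. Optimality is cheap
here because of a structural fact: spans within one document are
disjoint and ordered, so two candidate pairs that "cross" can never
both have positive overlap, every feasible matching is monotone, and
an alignment-style dynamic program over (reference index, prediction
index) finds the optimum in O(n·m).

Ties are resolved lexicographically: maximise total overlap, then the
number of matched pairs, then take the smallest (reference, predicted)
index sequence. Because candidate pairs are mutually non-crossing,
this tie-break is invariant under swapping the two documents, which
gives an exact symmetry: aligning (predicted, reference) transposes
the confusion matrix of aligning (reference, predicted). The test
suite checks the whole construction against an exhaustive brute-force
matcher on documents with up to six spans.

Matched spans yield one `(true label, predicted label)` row — a label
confusion on overlapping spans is a single row, never two `O` rows.
Unmatched reference spans yield `(label, O)`, unmatched predictions
`(O, label)`. Text outside all spans in *both* documents contributes
`(O, O)` units, by default one per token (a `"run"` granularity — one
unit per maximal unannotated stretch — is available; the unit that
produced the published `O` support is not stated anywhere, so this is
configurable and token-level counts should not be expected to
reproduce that support on real data).

## Scoring

Relaxed metrics come from the confusion matrix over all pairs:
per-class TP/FP/FN/TN as diagonal/column/row/complement, accuracy as
trace over total, macro averages unweighted over included classes,
weighted averages support-weighted. `include_O` defaults to true for
relaxed scoring (the published report has an `O` row) and the accuracy
is always computed over all pairs, whether or not `O` is included in
the per-class section. Exact-match scoring counts a predicted span as
TP iff an identical (start, end, label) exists; its "accuracy" is the
micro ratio TP/(TP+FP+FN), since there are no true negatives in that
regime. Chunk-level BIO scoring extracts maximal `B-`/`I-` chunks and
then scores chunk identity the same way; a dangling `I-` tag is
repaired by promotion to `B-` with a warning (a strict mode raises
instead), matching the lenient convention of common chunk evaluators.

Zero denominators yield 0 with a warning (configurable to raise).
Internal values keep full float precision; display rounding is
half-up to two decimals. One printed reference value is knowingly not
matched: the impression-row exact-match F1 prints as 0.79 while its
own printed counts (TP 307, FP 75, FN 83) give 0.7953, which rounds to
0.80 — the package reports the computed value and documents the
discrepancy rather than reproducing it. The same applies to the
exact-match micro accuracy (printed 0.71, computed 0.7156) and to
two OBS-A margins; these are artifacts of the upstream tool's own
rounding, not recomputable quantities.

## Prompt assembly

A prompt is the deterministic blank-line-separated concatenation of
instructions, numbered worked examples (`Example i: / Input: /
Output:`), the transitional phrase ("Here is the mammography report to
be tagged:"), the target report, and trailing control phrases that
force code-fenced output. Identical specs produce byte-identical
prompts; shots are kept in authored order (a seeded shuffle exists for
ablation). Token estimates use ceil(code points / 4), the usual
rule of thumb for subword tokenizers on Latin script; an exact
tokenizer can be plugged in. The packaged default components are
miniature English stand-ins that demonstrate the structure;
`study_scale_prompt()` assembles the full design-scale composition —
instructions grown to ~12,278 tokens of generated guideline lines, 165
generated single-sentence shots (~12.5k tokens), a ~265-token target —
whose total lands in the neighbourhood of the 26k-token budget the
design targets. Tests assert that estimate as a ±30% band, not an
equality: the heuristic and a production tokenizer genuinely differ.

Backends are synchronous `text → text` callables with retry handling;
the package ships a replay backend (fixture directory keyed by target
text), an identity echo, and an error-injecting mock. Live API
adapters satisfy the same contract and are outside the test surface by
design: everything here must run offline.

Rule-based corrections are ordered literal replacements; the default
ruleset removes four recurrent boilerplate mis-annotations observed on
Turkish technique/comparison sentences. Rules are matched in both
straight- and typographic-quote attribute renderings so only the span
tags named by a rule are touched, and application is idempotent.

## Synthetic corpus and error model

Generated documents are sectioned reports — a technique/comparison
header, findings sentences, impression lines — slot-filled from small
phrase pools in either an English or a Turkish-like template set.
Entity labels are drawn i.i.d. from a weight vector defaulting to the
frequency profile of the evaluation corpus this tooling targets
(supports 785 / 345 / 732 / 366 / 122 for ANAT / IMP / OBS-P / OBS-A /
OBS-U), and the default corpus size is 85 documents, the size of that
test set; a drawn `ANAT` followed by a drawn observation is packed
into one carrier sentence, which leaves the marginal label
distribution multinomial, so frequency-convergence tests have exact
binomial error bars. Documents default to 8–16 entities each.

What the generator does **not** emulate: real reports' vocabulary
breadth, discourse structure, negation scope ambiguity, typos, or
annotator disagreement. Passing tests therefore demonstrate that the
conversion/alignment/scoring machinery is exact and that planted error
rates flow through the pipeline unbiased — not that any model achieves
particular scores on real clinical text.

The perturbation model simulates predictions: per span — deletion,
label swap (uniform over the other four classes), boundary shift of up
to `max_shift` characters per side, clamped so the span keeps at least
one character of overlap with the original and never touches a
neighbouring span; plus spurious single-token insertions over text
unannotated in both documents (so they map cleanly to `(O, label)`
rows). All draws come from one seeded generator with a fixed,
documented draw order (per span: delete, swap, swap-target, start
shift, end shift; then per candidate token: insert, label), so every
run replays exactly; draws are consumed whether or not the event
fires, keeping streams aligned across configurations. The clamping
construction guarantees boundary-shifted corpora score a relaxed F1 of
exactly 1.0 while exact F1 falls — the separation the two regimes are
meant to exhibit.

## Problem sizes in tests and the acceptance script

The reference-table reproduction runs on the full 3,434-row pair
multiset (it is instant). Property checks use 150–200 seeded random
instances (documents ≤ 6 spans for the brute-force alignment oracle,
BIO streams ≤ 30 tokens for the chunker oracle). Recovery checks use
120 generated documents (~1,400–1,500 spans), enough for three-sigma
binomial bands near 1% width. These sizes were chosen so the whole
suite completes in seconds while keeping every statistical assertion
at three standard errors.

## Known limitations

- Alignment assumes both documents carry byte-identical text; there is
  no fuzzy reconciliation of model-rewritten reports (divergence is
  detected and warned on, not repaired).
- The `O`-unit granularity is a convention, not a recoverable fact;
  cross-tool comparisons of `O` supports are inherently approximate.
- BIO encoding requires span boundaries on token boundaries; spans
  produced by character-level boundary perturbation are generally not
  BIO-encodable and are evaluated via span-set or alignment routes.
- The correction engine is literal substring replacement by design
  (predictable, idempotent); it does not generalise across inflected
  variants of the boilerplate it targets.
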