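"""Run the full annotation loop offline with a mock backend.

A PerturbingBackend stands in for a cloud LLM: it answers each prompt
with the reference annotation of the target report, degraded by
configured error rates, inside a code fence.  The loop is: build prompt
-> annotate -> rule-based corrections -> parse -> align -> score.
"""

from promptner import (
    CorpusConfig,
    PerturbationConfig,
    PerturbingBackend,
    align_entities,
    annotate_report,
    apply_corrections,
    build_prompt,
    classification_metrics,
    default_prompt_spec,
    generate_corpus,
    parse_markup,
)

references = generate_corpus(CorpusConfig(n_docs=30, seed=31))
backend = PerturbingBackend(
    references,
    PerturbationConfig(p_label_swap=0.05, p_boundary_shift=0.2, seed=32),
    control_phrases=default_prompt_spec("x").control_phrases,
)

pairs = []
for ref in references:
    spec = default_prompt_spec(ref.text)
    prompt = build_prompt(spec)
    markup = annotate_report(prompt, backend, target_text=ref.text)
    markup = apply_corrections(markup)  # boilerplate fixes, no-op here
    predicted = parse_markup(markup, ref.doc_id)
    pairs.extend(align_entities(ref, predicted))

report = classification_metrics(pairs, include_O=False)
n_entity = sum(1 for p in pairs if p.y_true != "O" or p.y_pred != "O")
print(f"documents annotated: {len(references)}")
print(f"evaluation rows: {len(pairs)} ({n_entity} entity pairs)")
print(f"macro F1 {report.macro_avg[2]:.3f}   accuracy {report.accuracy:.3f}")

# With a 5% swap rate and some boundary noise, relaxed macro F1 stays in
# the low 0.9s: boundary shifts do not hurt relaxed scores, label swaps
# do.  Swap the mock for a live backend (same text -> text contract) and
# the rest of the loop is unchanged.
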