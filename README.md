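# promptner

A toolkit for prompt-based named-entity recognition (NER) on clinical
free text, built around the evaluation pipeline used for
span-annotated mammography reports. It is aimed at clinical-NLP
practitioners who annotate radiology reports with a large language
model (LLM) and need the surrounding machinery to be exact,
reproducible, and testable entirely offline:

- **Markup codec** — parse and render the inline HTML-span dialect
  (`<span class="OBS-P">nodular opacities</span>`) used for model
  input/output, with offset-exact round trips and extraction of fenced
  code-block responses.
- **Interchange** — Doccano-style JSONL (`[start, end, label]`
  triples), token-level BIO streams, delimited label-pair tables, and
  the punctuation-detachment preprocessing needed before tokenized
  exact-match evaluation.
- **Alignment** — turn a (reference, predicted) document pair into a
  label-pair table by exact maximum-overlap one-to-one span matching,
  with unannotated text contributing `(O, O)` units.
- **Scoring** — per-label precision/recall/F1, supports, accuracy,
  macro/weighted averages, and full confusion matrices with per-label
  TP/FP/FN/TN, under both relaxed (type + overlap) and exact
  (type + identical boundaries) matching, plus chunk-level scoring of
  BIO streams.
- **Prompting** — deterministic many-shot prompt assembly
  (instructions → shots → transitional phrase → target → control
  phrases), token budgeting, pluggable synchronous `text → text`
  backends (replay fixtures, identity echo, mocks), and rule-based
  post-correction of recurrent boilerplate mis-annotations.
- **Synthetic corpora** — sectioned mammography-style reports (English
  and Turkish-like template sets) with configurable entity-class
  frequencies, plus controlled error injection (boundary shifts, label
  swaps, deletions, spurious insertions) so every stage is testable
  with no real patient data.

## The model

Five entity classes are recognised — `ANAT` (anatomy), `IMP`
(impression), `OBS-P` / `OBS-A` / `OBS-U` (observation present /
absent / uncertain) — with `O` as the non-entity sentinel. For
counts TP, FP, FN per class,

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

Under **relaxed** matching a prediction is correct when its class
matches a reference entity whose character span overlaps it; under
**exact** matching the (start, end, label) triple must be identical.
Relaxed metrics derive from the (K+1)×(K+1) true × predicted confusion
matrix over aligned label pairs: per-class TP is the diagonal entry,
FP the column remainder, FN the row remainder, and accuracy the trace
over the total.

## Worked example

```python
from promptner import (CorpusConfig, PerturbationConfig, align_entities,
                       classification_metrics, generate_corpus,
                       perturb_corpus, render_report)

refs = generate_corpus(CorpusConfig(n_docs=60, seed=11))
preds = perturb_corpus(refs, PerturbationConfig(p_label_swap=0.10, seed=12))
pairs = [p for r, q in zip(refs, preds) for p in align_entities(r, q)]
print(render_report(classification_metrics(pairs)))
```

```
              precision     recall   f1-score    support

        ANAT       0.97       0.91       0.94        246
         IMP       0.89       0.94       0.92        108
           O       1.00       1.00       1.00       3070
       OBS-A       0.86       0.85       0.86        112
       OBS-P       0.94       0.92       0.93        215
       OBS-U       0.62       0.92       0.74         36

    accuracy                             0.98       3787
   macro avg       0.88       0.92       0.90       3787
weighted avg       0.98       0.98       0.98       3787
```

A 10% label-swap rate was injected and only labels were perturbed, so
per-label recall sits near 0.90, the `O` row stays perfect (boundaries
were untouched), and overall accuracy remains high because unannotated
tokens dominate. The `examples/` directory holds five short scripts —
markup round trips, relaxed scoring with a confusion matrix, exact vs
relaxed under boundary noise, many-shot prompt assembly, and the full
offline annotation loop with a mock backend.

A thin CLI mirrors the classic script-chain workflow as subcommands of
one entry point (`promptner convert | align | score | build-prompt |
annotate | correct | simulate`); run `promptner --help`.

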