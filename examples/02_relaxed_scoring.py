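"""Align a noisy prediction set against references and score it.

Generates a synthetic corpus, injects a 10% label-swap rate, aligns
predictions to references by maximum character overlap, and prints the
relaxed-match classification report with its confusion matrix.
"""

from promptner import (
    CorpusConfig,
    PerturbationConfig,
    align_entities,
    classification_metrics,
    confusion_matrix,
    generate_corpus,
    perturb_corpus,
    render_report,
)

references = generate_corpus(CorpusConfig(n_docs=60, seed=11))
predictions = perturb_corpus(references, PerturbationConfig(p_label_swap=0.10, seed=12))

pairs = [
    pair
    for ref, pred in zip(references, predictions)
    for pair in align_entities(ref, pred)
]
report = classification_metrics(pairs, include_O=True)
print(render_report(report))
print()
print(confusion_matrix(pairs).to_frame())

# Because only labels were swapped (boundaries untouched), each per-label
# recall sits near 0.90 = 1 - swap rate, off-diagonal confusion counts
# absorb the swaps, and the O row is perfect: unannotated tokens agree in
# both document sets.
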