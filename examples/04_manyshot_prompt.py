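"""Assemble a many-shot annotation prompt and inspect its budget.

The prompt is instructions -> worked examples -> transitional phrase ->
target report -> control phrases.  The packaged defaults are miniature;
study_scale_prompt() assembles the full design size (165 shots,
~12k-token instructions) from generated content.
"""

from promptner import build_prompt, default_prompt_spec, study_scale_prompt

spec = default_prompt_spec("Both breasts show scattered fibroglandular densities.")
prompt = build_prompt(spec)
print("--- miniature default prompt ---")
print(f"shots: {len(spec.shots)}   token estimate: {spec.token_estimate}")
print(prompt[: prompt.index("Example 2")].rstrip()[-400:])
print("...")
print(prompt[-220:])

full_spec, target_doc = study_scale_prompt(seed=0)
build_prompt(full_spec)
print("--- study-scale prompt ---")
print(f"shots: {len(full_spec.shots)}   token estimate: {full_spec.token_estimate}")
print(f"target report: {len(target_doc.spans)} reference entities")

# The token estimate uses the ceil(characters / 4) heuristic; the
# study-scale composition lands in the design neighbourhood of 26k
# tokens, the budget that motivated a large-context model.
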