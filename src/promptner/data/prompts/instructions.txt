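You are an expert annotator of mammography reports. Your task is to mark
every clinically meaningful entity in the report below using inline HTML
span tags, leaving all other text untouched.

Entity markup: wrap each entity in <span class="LABEL">...</span>, where
LABEL is exactly one of the following five classes.

Definitions:
- ANAT: an anatomical structure (e.g. a breast, quadrant, axilla, skin).
- OBS-P: an observation stated as present (a finding that is seen).
- OBS-A: an observation stated as absent (a finding explicitly negated).
- OBS-U: an observation whose presence is uncertain or equivocal.
- IMP: an impression or overall assessment statement (e.g. a category
  assignment or follow-up recommendation).

Annotation guidelines:
1. Annotate the minimal phrase that names the entity; do not include
   surrounding verbs or boilerplate.
2. Never nest one span inside another; spans must not overlap.
3. Do not annotate routine technique or comparison boilerplate sentences.
4. Copy the report text exactly; only insert span tags. Do not rewrite,
   translate, reorder or summarise any part of the report.
5. Every report sentence must appear in the output, annotated or not.

Worked examples of correctly annotated sentences follow.
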