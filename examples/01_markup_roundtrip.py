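"""Parse inline span markup into offsets and render it back.

Annotated reports travel as plain text with entities wrapped in
<span class="LABEL"> tags; parsing strips the tags and records
character offsets into the stripped text.
"""

from promptner import parse_markup, render_markup

markup = (
    'A <span class = "OBS-P">nodular opacity</span> is noted in the '
    '<span class="ANAT">right breast</span>. No '
    '<span class="OBS-A">suspicious mass</span> is identified.'
)

doc = parse_markup(markup, doc_id="example")
print("stripped text:", doc.text)
for span in doc.spans:
    print(f"  [{span.start:3d}, {span.end:3d})  {span.label:6s}  {doc.surface(span)!r}")
print("round trip identical:", parse_markup(render_markup(doc), "x").spans == doc.spans)

# Each line above is one entity: its half-open character offsets into the
# stripped text, its class, and the surface it covers.  Both attribute
# dialects (spaced and unspaced, straight or typographic quotes) parse
# identically; rendering always emits the canonical unspaced form.
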