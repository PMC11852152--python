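{"input": "Scattered fibroglandular densities are present in both breasts.", "output": "Scattered <span class=\"OBS-P\">fibroglandular densities</span> are present in <span class=\"ANAT\">both breasts</span>."}
{"input": "No suspicious mass or spiculated lesion is identified in the right breast.", "output": "No <span class=\"OBS-A\">suspicious mass</span> or <span class=\"OBS-A\">spiculated lesion</span> is identified in the <span class=\"ANAT\">right breast</span>."}
{"input": "A nodular opacity is noted in the upper outer quadrant of the left breast.", "output": "A <span class=\"OBS-P\">nodular opacity</span> is noted in the <span class=\"ANAT\">upper outer quadrant of the left breast</span>."}
{"input": "An asymmetric density in the left breast may represent summation artifact.", "output": "An <span class=\"OBS-U\">asymmetric density</span> in the <span class=\"ANAT\">left breast</span> may represent <span class=\"OBS-U\">summation artifact</span>."}
{"input": "Both axillae are unremarkable, without enlarged lymph nodes.", "output": "Both <span class=\"ANAT\">axillae</span> are unremarkable, without <span class=\"OBS-A\">enlarged lymph nodes</span>."}
{"input": "Impression: benign-appearing calcifications, routine screening is recommended.", "output": "Impression: <span class=\"IMP\">benign-appearing calcifications, routine screening is recommended</span>."}
{"input": "Skin and nipple are normal; scattered benign calcifications are seen.", "output": "<span class=\"ANAT\">Skin</span> and <span class=\"ANAT\">nipple</span> are normal; scattered <span class=\"OBS-P\">benign calcifications</span> are seen."}
{"input": "Assessment: probably benign finding, short-interval follow-up is advised.", "output": "Assessment: <span class=\"IMP\">probably benign finding, short-interval follow-up is advised</span>."}
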