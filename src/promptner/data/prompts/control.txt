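###Do not forget to output in a code snippet window.
###Why didn’t you output in a code snippet window?
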