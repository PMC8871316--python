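category,probably_malignant,indeterminate,probably_benign
probably_malignant,579,15,170
indeterminate,17,5,5
probably_benign,225,40,291
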