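category,probably_malignant,indeterminate,probably_benign
probably_malignant,1021,29,254
indeterminate,29,12,11
probably_benign,377,73,505
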