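category,negative,indeterminate,positive
negative,611,445,100
indeterminate,1,83,182
positive,0,0,161
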