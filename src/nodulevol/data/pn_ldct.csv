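category,negative,indeterminate,positive
negative,1308,735,160
indeterminate,3,108,217
positive,0,0,184
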