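actual,positive,negative
positive,56,37
negative,23,84
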