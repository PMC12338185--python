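# Brand and trade names treated as the same active substance
TUKYSA
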