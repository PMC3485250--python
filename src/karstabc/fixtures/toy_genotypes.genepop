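toy 5-individual microsatellite panel (synthetic, hand-checked)
locusA
locusB
Pop
i1 , 010010 008008
i2 , 010012 008008
i3 , 012012 008008
i4 , 010012 008008
i5 , 012014 008008
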