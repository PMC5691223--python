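# synthetic reference serpin: fixture annotations define ground truth
hinge_start: 280
p1_position: 296
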