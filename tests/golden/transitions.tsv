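from	to	inherited	newly_generated	undetermined
early	late	18	0	0
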