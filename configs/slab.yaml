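# Slab-images phantom experiment: 187 eight-row slabs, linear model on the
# surrogate value and derivative, fitted against the true reference.
regime: slab
seed: 1
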