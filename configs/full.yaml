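# Full-images phantom experiment: 10 noisy frames, one cos^4 cycle,
# periodic B-spline phase model fitted against the true reference.
regime: full
seed: 1
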