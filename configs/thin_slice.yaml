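# Thin-slice phantom experiment: 3010 single rows in alternating sweeps,
# alternating fit / averaging-MCIR scheme (no reference image).
regime: thin_slice
seed: 1
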