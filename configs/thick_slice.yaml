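# Thick-slice phantom experiment: 1500 overlapping 5-px-FWHM rows,
# alternating fit / super-resolution-MCIR scheme (no reference image).
regime: thick_slice
seed: 1
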