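region	iron_mg_per_100g
globus_pallidus	21.30
red_nucleus	19.48
substantia_nigra	18.46
putamen	13.32
dentate_nucleus	10.35
caudate_nucleus	9.28
thalamus	4.76
frontal_white_matter	4.24
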