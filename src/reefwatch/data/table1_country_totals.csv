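country,total_new_area_km2
C,14.52
V,0.54
T,0.06
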