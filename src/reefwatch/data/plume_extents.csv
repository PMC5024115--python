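reef_name,n_images_examined,n_images_with_plume,extent_km2
Mischief Reef,205,70,2135
Subi Reef,129,43,842
Fiery Cross Reef,105,45,1404
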