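species_set,fossil_group,age_min_my,age_max_my,citation
Eumastacidae;Pyrgacrididae,Eumastacidae,145,163.5,oldest definitive eumastacid fossil (Jurassic)
Lentulidae;Pamphagidae;Tridactylidae,Tridactylidae,98.7,108,oldest tridactylid fossil
Lentulidae;Pamphagidae,Acridoidea,33.9,38,oldest acridoid fossil
Lentulidae;Pamphagodidae;Pneumoridae;Prophalangopsidae,Prophalangopsidae,182,201,oldest prophalangopsid fossil (Jurassic)
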