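taxon,NQ,MNQ,MOQ,MMOQ,ND,CNQ,MAQ,DMAQ,BQ,ABQ
Cyphophthalmus_duricorius,D,D,N,N,N,D,N,N,N,N
Siro_exilis,D,D,N,N,N,D,N,N,N,N
Austropurcellia_forsteri,D,D,N,N,N,D,N,N,N,N
Stylocellidae_sp,D,D,D,N,D,N,N,N,N,N
Travunioidea_spp,N,N,N,N,N,N,N,N,N,N
Triaenonychoidea_spp,N,N,N,N,N,N,N,N,N,N
Phalangodidae_spp,N,N,N,N,N,N,N,N,N,N
Stygnommatidae_spp,N,N,N,N,N,N,N,N,N,N
Stygnopsidae_spp,N,N,N,N,N,N,N,N,N,N
Manaosbiidae_spp,N,N,N,N,N,N,N,N,N,P
Cosmetidae_spp,N,N,N,N,N,N,N,N,N,P
Gonyleptidae_spp,N,N,N,N,N,N,N,N,N,P
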