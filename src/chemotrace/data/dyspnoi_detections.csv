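taxon,NQ,MNQ,MOQ,MMOQ,ND,CNQ,MAQ,DMAQ,BQ,ABQ
Dicranolasma_scabrum,N,N,N,N,N,N,N,N,N,N
Dicranolasma_soerensii,N,N,N,N,N,N,N,N,N,N
Carinostoma_carinatum,D,D,N,N,N,N,N,N,N,N
Carinostoma_elegans,D,D,N,N,N,N,N,N,N,N
Carinostoma_ornatum,D,D,N,N,N,N,N,N,N,N
Centetostoma_sp,D,D,N,N,N,N,N,N,N,N
Histricostoma_argenteolunatum,D,D,N,N,N,N,N,N,N,N
Histricostoma_dentipalpe,D,D,N,N,N,N,N,N,N,N
Mediostoma_humerale,D,D,N,N,N,N,N,N,N,N
Mitostoma_chrysomelas,N,N,N,N,N,N,N,N,N,N
Nemastoma_b_bidentatum,D,D,N,N,N,N,N,N,N,N
Nemastoma_b_relictum,D,D,N,N,N,N,N,N,N,N
Nemastoma_b_sparsum,D,D,N,N,N,N,N,N,N,N
Nemastoma_bidentatum_ssp_nov,D,D,P,N,N,P,P,N,N,N
Nemastoma_bimaculatum,I,I,I,I,I,I,I,I,I,I
Nemastoma_dentigerum,D,D,N,N,N,P,N,N,N,N
Nemastoma_lugubre,D,D,N,N,N,P,N,N,N,N
Nemastoma_schuelleri,D,D,N,N,N,P,N,N,N,N
Nemastoma_triste,D,D,N,P,N,P,P,N,N,N
Paranemastoma_bicuspidatum,D,D,D,D,D,N,D,D,N,N
Paranemastoma_quadripunctatum,D,D,D,D,D,N,D,D,N,N
Dendrolasma_dentipalpe,N,N,N,N,N,N,N,N,N,N
Dendrolasma_mirabile,N,N,N,N,N,N,N,N,N,N
Ortholasma_colossus,N,N,N,N,N,N,N,N,N,N
Ortholasma_coronadense,N,N,N,N,N,N,N,N,N,N
Ortholasma_levipes,N,N,N,N,N,N,N,N,N,N
Ortholasma_rugosum,N,N,N,N,N,N,N,N,N,N
Trogulus_tingiformis,N,N,N,N,N,N,N,N,N,N
Trogulus_sp,N,N,N,N,N,N,N,N,N,N
Ischyropsalis_kollari,N,N,N,N,N,N,N,N,N,N
Hesperonemastoma_modestum,D,D,N,N,N,D,N,N,N,N
Sabacon_sp,I,I,I,I,I,I,I,I,I,I
Taracus_sp,N,N,N,N,N,N,N,N,N,N
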