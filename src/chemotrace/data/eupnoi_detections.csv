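taxon,NQ,MNQ,MOQ,MMOQ,ND,CNQ,MAQ,DMAQ,BQ,ABQ
Phalangium_opilio,D,D,N,N,N,N,N,N,N,N
Rilaena_triangularis,D,N,N,N,N,N,N,N,D,N
Lacinius_dentiger,N,N,N,N,N,N,N,N,N,N
Lacinius_ephippiatus,N,D,N,N,N,N,N,N,N,N
Lacinius_horridus,N,D,N,N,N,N,N,N,N,N
Mitopus_morio,N,N,N,N,N,N,N,N,N,N
Oligolophus_tridens,N,D,N,N,N,N,N,N,N,N
Odiellus_sp,I,I,I,I,I,I,I,I,I,I
Lophopilio_palpinalis,D,D,N,N,N,N,N,N,N,N
Megabunus_armatus,N,N,N,N,N,N,N,N,D,N
Megabunus_bergomas,N,N,N,N,N,N,N,N,D,N
Megabunus_lesserti,N,N,N,N,N,N,N,N,D,N
Megabunus_rhinoceros,N,N,N,N,N,N,N,N,D,N
Megabunus_vignai,N,N,N,N,N,N,N,N,D,N
Platybunus_bucephalus,N,N,N,N,N,N,N,N,D,N
Egaenus_convexus,N,N,N,N,N,N,N,N,N,N
Opilio_canestrinii,N,N,N,N,N,N,N,N,N,N
Opilio_dinaricus,N,N,N,N,N,N,N,N,N,N
Opilio_parietinus,N,N,N,N,N,N,N,N,N,N
Opilio_ruzickai,I,I,I,I,I,I,I,I,M,M
Opilio_saxatilis,N,N,N,N,N,N,N,N,N,N
Protolophus_niger,N,N,N,N,N,N,N,N,N,N
Protolophus_singularis,N,N,N,N,N,N,N,N,N,N
Leiobunum_blackwalli,N,N,N,N,N,N,N,N,N,N
Leiobunum_limbatum,N,N,N,N,N,N,N,N,N,N
Leiobunum_roseum,N,N,N,N,N,N,N,N,N,N
Leiobunum_rotundum,N,N,N,N,N,N,N,N,N,N
Leiobunum_rupestre,N,N,N,N,N,N,N,N,N,N
Leiobunum_subalpinum,N,N,N,N,N,N,N,N,N,N
Leiobunum_sp_nov,N,N,N,N,N,N,N,N,N,N
Nelima_sempronii,N,N,N,N,N,N,N,N,N,N
Nelima_troglodytes,N,N,N,N,N,N,N,N,N,N
Astrobunus_dinaricus,N,N,N,N,N,N,N,N,N,N
Astrobunus_helleri,N,N,N,N,N,N,N,N,N,N
Astrobunus_kochi,N,N,N,N,N,N,N,N,N,N
Astrobunus_laevipes,N,N,N,N,N,N,N,N,N,N
Gyas_annulatus,N,N,N,N,N,N,N,N,D,N
Gyas_titanus,N,N,N,N,N,N,N,N,D,N
Amilenus_aurantiacus,N,N,N,N,N,N,N,N,D,N
Dicranopalpus_gasteinensis,N,N,N,N,N,N,N,N,I,N
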