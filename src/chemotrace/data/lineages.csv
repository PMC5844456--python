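taxon,suborder,superfamily,family,subfamily,genus
Phalangium_opilio,Eupnoi,Phalangioidea,Phalangiidae,Phalangiinae,Phalangium
Rilaena_triangularis,Eupnoi,Phalangioidea,Phalangiidae,Phalangiinae,Rilaena
Lacinius_dentiger,Eupnoi,Phalangioidea,Phalangiidae,Oligolophinae,Lacinius
Lacinius_ephippiatus,Eupnoi,Phalangioidea,Phalangiidae,Oligolophinae,Lacinius
Lacinius_horridus,Eupnoi,Phalangioidea,Phalangiidae,Oligolophinae,Lacinius
Mitopus_morio,Eupnoi,Phalangioidea,Phalangiidae,Oligolophinae,Mitopus
Oligolophus_tridens,Eupnoi,Phalangioidea,Phalangiidae,Oligolophinae,Oligolophus
Odiellus_sp,Eupnoi,Phalangioidea,Phalangiidae,Oligolophinae,Odiellus
Lophopilio_palpinalis,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Lophopilio
Megabunus_armatus,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Megabunus
Megabunus_bergomas,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Megabunus
Megabunus_lesserti,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Megabunus
Megabunus_rhinoceros,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Megabunus
Megabunus_vignai,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Megabunus
Platybunus_bucephalus,Eupnoi,Phalangioidea,Phalangiidae,Platybuninae,Platybunus
Egaenus_convexus,Eupnoi,Phalangioidea,Phalangiidae,Opilioninae,Egaenus
Opilio_canestrinii,Eupnoi,Phalangioidea,Phalangiidae,Opilioninae,Opilio
Opilio_dinaricus,Eupnoi,Phalangioidea,Phalangiidae,Opilioninae,Opilio
Opilio_parietinus,Eupnoi,Phalangioidea,Phalangiidae,Opilioninae,Opilio
Opilio_ruzickai,Eupnoi,Phalangioidea,Phalangiidae,Opilioninae,Opilio
Opilio_saxatilis,Eupnoi,Phalangioidea,Phalangiidae,Opilioninae,Opilio
Protolophus_niger,Eupnoi,Phalangioidea,Protolophidae,,Protolophus
Protolophus_singularis,Eupnoi,Phalangioidea,Protolophidae,,Protolophus
Leiobunum_blackwalli,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Leiobunum_limbatum,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Leiobunum_roseum,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Leiobunum_rotundum,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Leiobunum_rupestre,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Leiobunum_subalpinum,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Leiobunum_sp_nov,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Leiobunum
Nelima_sempronii,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Nelima
Nelima_troglodytes,Eupnoi,Phalangioidea,Sclerosomatidae,Leiobuninae,Nelima
Astrobunus_dinaricus,Eupnoi,Phalangioidea,Sclerosomatidae,Sclerosomatinae,Astrobunus
Astrobunus_helleri,Eupnoi,Phalangioidea,Sclerosomatidae,Sclerosomatinae,Astrobunus
Astrobunus_kochi,Eupnoi,Phalangioidea,Sclerosomatidae,Sclerosomatinae,Astrobunus
Astrobunus_laevipes,Eupnoi,Phalangioidea,Sclerosomatidae,Sclerosomatinae,Astrobunus
Gyas_annulatus,Eupnoi,Phalangioidea,Sclerosomatidae,Gyantinae,Gyas
Gyas_titanus,Eupnoi,Phalangioidea,Sclerosomatidae,Gyantinae,Gyas
Amilenus_aurantiacus,Eupnoi,Phalangioidea,Dicranopalpus_group,,Amilenus
Dicranopalpus_gasteinensis,Eupnoi,Phalangioidea,Dicranopalpus_group,,Dicranopalpus
Dicranolasma_scabrum,Dyspnoi,Troguloidea,Dicranolasmatidae,,Dicranolasma
Dicranolasma_soerensii,Dyspnoi,Troguloidea,Dicranolasmatidae,,Dicranolasma
Carinostoma_carinatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Carinostoma
Carinostoma_elegans,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Carinostoma
Carinostoma_ornatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Carinostoma
Centetostoma_sp,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Centetostoma
Histricostoma_argenteolunatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Histricostoma
Histricostoma_dentipalpe,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Histricostoma
Mediostoma_humerale,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Mediostoma
Mitostoma_chrysomelas,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Mitostoma
Nemastoma_b_bidentatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_b_relictum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_b_sparsum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_bidentatum_ssp_nov,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_bimaculatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_dentigerum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_lugubre,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_schuelleri,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Nemastoma_triste,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Nemastoma
Paranemastoma_bicuspidatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Paranemastoma
Paranemastoma_quadripunctatum,Dyspnoi,Troguloidea,Nemastomatidae,Nemastomatinae,Paranemastoma
Dendrolasma_dentipalpe,Dyspnoi,Troguloidea,Nemastomatidae,Ortholasmatinae,Dendrolasma
Dendrolasma_mirabile,Dyspnoi,Troguloidea,Nemastomatidae,Ortholasmatinae,Dendrolasma
Ortholasma_colossus,Dyspnoi,Troguloidea,Nemastomatidae,Ortholasmatinae,Ortholasma
Ortholasma_coronadense,Dyspnoi,Troguloidea,Nemastomatidae,Ortholasmatinae,Ortholasma
Ortholasma_levipes,Dyspnoi,Troguloidea,Nemastomatidae,Ortholasmatinae,Ortholasma
Ortholasma_rugosum,Dyspnoi,Troguloidea,Nemastomatidae,Ortholasmatinae,Ortholasma
Trogulus_tingiformis,Dyspnoi,Troguloidea,Trogulidae,,Trogulus
Trogulus_sp,Dyspnoi,Troguloidea,Trogulidae,,Trogulus
Ischyropsalis_kollari,Dyspnoi,Ischyropsalidoidea,Ischyropsalididae,,Ischyropsalis
Hesperonemastoma_modestum,Dyspnoi,Ischyropsalidoidea,Sabaconidae,,Hesperonemastoma
Sabacon_sp,Dyspnoi,Ischyropsalidoidea,Sabaconidae,,Sabacon
Taracus_sp,Dyspnoi,Ischyropsalidoidea,Sabaconidae,,Taracus
Cyphophthalmus_duricorius,Cyphophthalmi,,Sironidae,,Cyphophthalmus
Siro_exilis,Cyphophthalmi,,Sironidae,,Siro
Austropurcellia_forsteri,Cyphophthalmi,,Pettalidae,,Austropurcellia
Stylocellidae_sp,Cyphophthalmi,,Stylocellidae,,
Travunioidea_spp,Laniatores,Travunioidea,,,
Triaenonychoidea_spp,Laniatores,Triaenonychoidea,,,
Phalangodidae_spp,Laniatores,,Phalangodidae,,
Stygnommatidae_spp,Laniatores,,Stygnommatidae,,
Stygnopsidae_spp,Laniatores,Gonyleptoidea,Stygnopsidae,,
Manaosbiidae_spp,Laniatores,Gonyleptoidea,Manaosbiidae,,
Cosmetidae_spp,Laniatores,Gonyleptoidea,Cosmetidae,,
Gonyleptidae_spp,Laniatores,Gonyleptoidea,Gonyleptidae,,
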