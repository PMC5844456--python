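((
  (Cyphophthalmus_duricorius,Siro_exilis)Sironidae,
  Austropurcellia_forsteri,
  Stylocellidae_sp
 )Cyphophthalmi,
 (
  (
   (Travunioidea_spp,Triaenonychoidea_spp)Insidiatores,
   (Phalangodidae_spp,
    Stygnommatidae_spp,
    (Stygnopsidae_spp,Manaosbiidae_spp,Cosmetidae_spp,Gonyleptidae_spp)Gonyleptoidea
   )Grassatores
  )Laniatores,
  (
   (
    Caddoidea_placeholder,
    (
     Neopilionidae_placeholder,
     Monoscutidae_placeholder,
     (
      (Phalangium_opilio,Rilaena_triangularis)Phalangiinae,
      ((Lacinius_dentiger,Lacinius_ephippiatus,Lacinius_horridus)Lacinius,
       Mitopus_morio,Oligolophus_tridens,Odiellus_sp)Oligolophinae,
      (Lophopilio_palpinalis,
       (Megabunus_armatus,Megabunus_bergomas,Megabunus_lesserti,Megabunus_rhinoceros,Megabunus_vignai)Megabunus,
       Platybunus_bucephalus)Platybuninae,
      (Egaenus_convexus,
       (Opilio_canestrinii,Opilio_dinaricus,Opilio_parietinus,Opilio_ruzickai,Opilio_saxatilis)Opilio
      )Opilioninae
     )Phalangiidae,
     (
      ((Leiobunum_blackwalli,Leiobunum_limbatum,Leiobunum_roseum,Leiobunum_rotundum,Leiobunum_rupestre,Leiobunum_subalpinum,Leiobunum_sp_nov)Leiobunum,
       (Nelima_sempronii,Nelima_troglodytes)Nelima)Leiobuninae,
      (Astrobunus_dinaricus,Astrobunus_helleri,Astrobunus_kochi,Astrobunus_laevipes)Sclerosomatinae,
      (Gyas_annulatus,Gyas_titanus)Gyantinae
     )Sclerosomatidae,
     (Amilenus_aurantiacus,Dicranopalpus_gasteinensis)Dicranopalpus_group,
     (Protolophus_niger,Protolophus_singularis)Protolophidae
    )Phalangioidea
   )Eupnoi,
   (
    Acropsopilionidae_placeholder,
    (
     (Ischyropsalis_kollari,
      (Hesperonemastoma_modestum,Sabacon_sp,Taracus_sp)Sabaconidae
     )Ischyropsalidoidea,
     (
      Nipponopsalididae_placeholder,
      (
       (
        ((Dendrolasma_dentipalpe,Dendrolasma_mirabile)Dendrolasma,
         (Ortholasma_colossus,Ortholasma_coronadense,Ortholasma_levipes,Ortholasma_rugosum)Ortholasma
        )Ortholasmatinae,
        ((Carinostoma_carinatum,Carinostoma_elegans,Carinostoma_ornatum)Carinostoma,
         Centetostoma_sp,
         (Histricostoma_argenteolunatum,Histricostoma_dentipalpe)Histricostoma,
         Mediostoma_humerale,
         Mitostoma_chrysomelas,
         (Nemastoma_b_bidentatum,Nemastoma_b_relictum,Nemastoma_b_sparsum,Nemastoma_bidentatum_ssp_nov,Nemastoma_bimaculatum,Nemastoma_dentigerum,Nemastoma_lugubre,Nemastoma_schuelleri,Nemastoma_triste)Nemastoma,
         (Paranemastoma_bicuspidatum,Paranemastoma_quadripunctatum)Paranemastoma
        )Nemastomatinae
       )Nemastomatidae,
       ((Dicranolasma_scabrum,Dicranolasma_soerensii)Dicranolasmatidae,
        (Trogulus_tingiformis,Trogulus_sp)Trogulidae
       )
      )Troguloidea
     )
    )
   )Dyspnoi
  )Palpatores
 )Phalangida
)Opiliones;
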