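# Checked-in manifest for the packaged composite harvestman tree.
# Used by the test suite to pin leaf counts, clade memberships, and
# polytomy degrees of the fixture; edit together with composite_tree.nwk.
#
# Note on placements the source trees leave open:
#   - Protolophidae is attached to the Phalangioidea polytomy (its position
#     is not resolved by the five-group arrangement used for Phalangioidea).
#   - Hesperonemastoma is placed inside Sabaconidae.
#   - Placeholder leaves stand for lineages with no chemical data and are
#     coded missing when bound to a character matrix.
n_leaves: 90
root: Opiliones
root_children: [Cyphophthalmi, Phalangida]
placeholders:
  - Caddoidea_placeholder
  - Neopilionidae_placeholder
  - Monoscutidae_placeholder
  - Acropsopilionidae_placeholder
  - Nipponopsalididae_placeholder
clade_leaf_counts:
  Cyphophthalmi: 4
  Laniatores: 8
  Gonyleptoidea: 4
  Eupnoi: 43
  Phalangioidea: 42
  Phalangiidae: 21
  Platybuninae: 7
  Sclerosomatidae: 15
  Gyantinae: 2
  Dicranopalpus_group: 2
  Dyspnoi: 35
  Nemastomatinae: 19
  Ischyropsalidoidea: 4
  Palpatores: 78
  Phalangida: 86
polytomy_degrees:
  Cyphophthalmi: 3
  Phalangioidea: 6
  Phalangiidae: 4
  Oligolophinae: 4
  Platybuninae: 3
  Megabunus: 5
  Opilio: 5
  Sclerosomatidae: 3
  Leiobunum: 7
  Sclerosomatinae: 4
  Gonyleptoidea: 4
  Nemastomatinae: 7
  Nemastoma: 9
  Sabaconidae: 3
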