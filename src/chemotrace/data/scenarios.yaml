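# Competing origin hypotheses for quinone evolution in harvestman scent
# glands, encoded as constrained parsimony reconstructions.
#
# Each scenario lists named origins; an origin maps to one or more clades
# (internal-node or leaf labels of the composite tree) whose stem edges are
# the only edges on which an absent->present change is permitted.  With
# required: true, every listed stem edge must carry a gain.  The number of
# origin events of a reconstruction is the number of named origins whose
# edge set carries at least one gain, so an origin realised by two
# non-sister clades (the dyspnoan naphthoquinone producers) still counts
# once.  Losses are never constrained.
#
# "Opiliones" names the root; a gain there is charged on the virtual stem
# above the root (common ancestry of the whole order).
- label: NQ-A
  character: NQ-class
  required: true
  origins:
    Cyphophthalmi: [Cyphophthalmi]
    Dyspnoi: [Nemastomatinae, Hesperonemastoma_modestum]
    Phalangiidae: [Phalangiidae]
- label: NQ-B
  character: NQ-class
  required: true
  origins:
    Cyphophthalmi: [Cyphophthalmi]
    Palpatores: [Palpatores]
- label: NQ-C
  character: NQ-class
  required: true
  origins:
    Opiliones: [Opiliones]
- label: BQ-D
  character: BQ-class
  required: true
  origins:
    Gonyleptoidea: [Gonyleptoidea]
    Gyantinae: [Gyantinae]
    Dicranopalpus_group: [Dicranopalpus_group]
    Phalangiidae: [Phalangiidae]
- label: BQ-E
  character: BQ-class
  required: true
  origins:
    Palpatores: [Palpatores]
    Gonyleptoidea: [Gonyleptoidea]
- label: BQ-F
  character: BQ-class
  required: true
  origins:
    Phalangida: [Phalangida]
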