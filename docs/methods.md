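# Methods

## Character coding

The raw data are taxon × compound detection grids with a five-valued cell
alphabet: detected, not detected, partial ("found in a part of the
analysed species"), inconclusive ("no conclusive data"), and missing ("data
missing"). Coding policies collapse compound groups into binary characters:

- **NQ-class** = {NQ, MNQ, MOQ, MMOQ, ND, CNQ}. The naphthalenediol (ND)
  is grouped with the naphthoquinones because it co-occurs with them in
  the dyspnoan producers and the one cyphophthalmid naphthalenedione is
  treated the same way in the source compilation; the grouping is a policy
  field and can be overridden.
- **BQ-class** = {BQ, ABQ}.
- **AQ-class** = {MAQ, DMAQ}, available via the `with-aq` policy but
  excluded from the default pair: the reconstruction question concerns
  naphtho- and benzoquinones.

Collapse rule per taxon and character: any detected or *partial* cell ⇒
present (a partial detection is positive evidence at that terminal); else
any not-detected cell ⇒ absent; else (only inconclusive/missing cells) ⇒
missing. Consequently an all-"?" row is missing, and the one row whose
benzoquinone columns are dashes ("data missing") codes missing, not
absent. The rule depends only on the multiset of cells in the group, so
binarization is idempotent and invariant to row/column permutation.

Terminals are kept at the resolution the tables print: "sp."/"ssp." rows
are distinct terminals, and the grouped Laniatores rows (e.g. "more than
30 species" of Gonyleptidae) are single family-level terminals. Rank
metadata (suborder … genus) travels in a sidecar CSV and drives the
summary filters.

## The composite tree

The packaged tree transcribes a published composite arrangement:
Cyphophthalmi sister to Laniatores + Palpatores (Eupnoi + Dyspnoi);
Phalangioidea as a polytomy of its five named groups; Phalangiidae and
Sclerosomatidae subfamilies as polytomies; multi-species genera as
genus-level polytomies; Dyspnoi with Ischyropsalidoidea sister to
Nipponopsalididae + Troguloidea; Laniatores with Gonyleptoidea nested in
Grassatores. Protolophidae is not placed by the five-group arrangement
and is attached to the Phalangioidea polytomy; Hesperonemastoma is placed
inside Sabaconidae. Five lineages with no chemical data anywhere
(Caddoidea, Neopilionidae, Monoscutidae, Nipponopsalididae,
Acropsopilionidae) are single placeholder leaves coded missing. A
checked-in manifest pins leaf counts, clade memberships, and polytomy
degrees; the test suite compares tree and manifest.

Polytomies are hard: the Sankoff recursion sums over all children of a
multifurcation, and no resolution enumeration is attempted. Branch
lengths are ignored throughout — the method is parsimony.

## Ancestral reconstruction

Costs are exact (integer/Fraction) end to end; infeasible assignments are
priced at infinity, never approximated. The default step matrix charges
gains 2 and losses 1, encoding the asymmetry between evolving a
multi-step biosynthetic pathway and losing it by a single inactivation.
The virtual stem above the root is fixed to `absent` by default, so a
root origin is charged as a gain; a free root is one flag away for
sensitivity analysis. Missing leaves get zero cost in every state (the
standard Sankoff treatment), which makes "add a dataless leaf" provably
cost-neutral — a property test asserts it.

MPR enumeration backtracks through the DP tables in a fixed order (step
matrix state order × preorder node index), so output is deterministic;
every enumerated reconstruction is re-summed and asserted equal to the DP
optimum, and a cap (default 10 000) truncates with an explicit flag
rather than silently. Exact minimum and maximum gain counts over the full
MPR set are computed without enumeration by running the same DP over
lexicographically ordered (cost, ±gains) pairs; lexicographic order is
translation-invariant under componentwise addition, which is exactly the
condition for the dynamic programme to remain exact.

On the packaged fixtures (gain 2 : loss 1, stem absent) the benzoquinone
character costs 12 with a unique MPR of 5 gains, and the naphthoquinone
character costs 14 with a unique MPR of 4 gains. These are the numbers
the acceptance script recomputes; the test suite asserts only the
published lower bound (benzoquinone origins ≥ 2), because the printed
tables resolve more structure than the schematic published
reconstruction.

## Origin scenarios

A scenario is a set of named origins, each a group of one or more clade
stems; gains are forbidden off the listed stems and (when `required`)
forced on each of them, while losses are never constrained. The *origin
events* of a reconstruction count groups carrying at least one gain, so a
hypothesised single origin realised on two non-sister clades of the
working tree — the dyspnoan naphthoquinone producers, nemastomatines plus
Hesperonemastoma — counts once. Requiring a gain on every listed stem is
implemented by restricting that edge's transition set in the DP, so
constrained optima need no post-filtering; an infeasible scenario is a
result (`feasible=False`), not an exception. Scenario definitions ship as
editable YAML because the published hypothesis panels are schematic; the
benzoquinone multiple-origin panel is encoded with a Phalangiidae-stem
origin (its platybunine + *Rilaena* + *Amilenus* + Gyantinae producers
have no exclusive common ancestor on the composite tree).

Ranking is by constrained parsimony cost only — no likelihoods, no
information criteria — with deterministic (cost, label) ordering.

## Retention indices and identification

Kovats RI by linear interpolation between the bracketing ladder alkanes,
`RI = 100·n0 + 100·(n1−n0)·(t−t0)/(t1−t0)`; the (n1−n0) factor reduces to
the familiar formula on gapless ladders (the reference mix is C9–C36,
one alkane per carbon) and keeps ladder points exact when a ladder has
gaps. Linear rather than logarithmic interpolation matches the linear
temperature programme. No extrapolation beyond the ladder by default; an
opt-in flag extends the terminal segments with a warning.

Identification: a library entry is a candidate when |RI difference| ≤
`ri_tol` (default 10 index units — conservative against the 41-unit
spread of the closest anthraquinone isomer pair) and at least
`min_ion_frac` (default 0.5) of the peak's observed ions occur among the
entry's diagnostic ions plus molecular ion at unit mass resolution. The
match fraction is taken over the *observed* ions: a reference spectrum
lists many minor fragments a weak peak will not show, and the packaged
worked example (an anthraquinone peak showing four ions) identifies
correctly only under this convention. Ranking is (RI distance, descending
ion overlap, code); intensity-weighted spectral similarity is out of
scope.

## Synthetic data

The trait simulator runs a two-state continuous-time Markov chain
root-to-tips from `absent` with gain rate q01 and loss rate q10 per unit
branch length (default length 1 per edge), drawing exact event times, so
the asymmetric-rate regime analogous to the 2:1 step matrix is
expressible. A conditioned `single_gain` mode places exactly one gain on
a uniformly chosen edge — the regime where parsimony recovery is provably
exact, which the recovery experiment verifies replicate by replicate.
Random trees grow by sequential leaf attachment with a polytomy-merge
probability, exercising the hard-polytomy code path. Detection-table
fixtures give each present tip a detected cell for one compound of the
character's class and can blank cells to "inconclusive" at a chosen rate;
at noise 0 the fixture round-trips through binarization to the simulated
tip states exactly. GC fixtures back-compute retention times from library
RIs on a linear ladder so the round trip through `kovats_ri` and
`identify` is exact by construction.

Defaults for the recovery experiments (12–24 leaves, polytomy probability
0.25–0.3, rates of order 0.1–0.2 per edge) keep replicates in the regime
of the empirical data — a handful of events on a tree of moderate size —
and the problem sizes reported by the acceptance script (90-leaf fixture
tree; 2 000 conditioned replicates on 12-leaf trees) are the sizes at
which all results in this repository were produced.

What the simulations do *not* emulate: correlated detection failures
(real "inconclusive" rows cluster by taxon, not i.i.d. by cell),
rate variation across lineages, branch-length information, and mass
spectra beyond diagnostic-ion lists. Passing recovery tests therefore
validate the inference machinery, not the biological adequacy of the 2:1
cost choice.

## Known limitations

- Parsimony only: no likelihood ASR, no stochastic mapping, no use of
  branch lengths; cost asymmetry is a modelling choice, not an estimate.
- The composite tree is a transcription of a schematic arrangement; edits
  to the Newick fixture (and manifest) change the reconstruction, which
  is the point of shipping them as data.
- The published single-root-origin picture for naphthoquinones is not an
  unconstrained optimum on these tables; it is represented honestly as
  the constrained scenario NQ-C and ranked against the alternatives.
- Identification is library-bound: a compound absent from the reference
  library (or lacking an RI, like the alkylated-benzoquinone class entry)
  can never be called.
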