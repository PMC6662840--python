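# Methods

## Scope and data model

`dollotrace` chains four inferences — synteny-anchored positional
orthology, ORF-integrity/pseudogene classification, Dollo-parsimony
gain/loss reconstruction on a timed species tree, and loss-pattern
co-evolution — plus a qPCR relative-quantification stage. It consumes
per-species gene-coordinate maps (GFF3 gene records, BED6, or a pinned
TSV dialect), coding models (exon intervals plus spliced CDS), a rooted
Newick tree with branch lengths in million years (MY), presence-state
matrices, and long-format Ct tables. Genome screening, sequence
alignment-based phylogenetics, and BLAST searches are out of scope: the
package starts from gene maps and CDS the user has already extracted.

Presence states form a five-letter alphabet: `INTACT`, `PSEUDOGENE`,
`ABSENT`, `UNKNOWN`, `HOMOLOG_UNRESOLVED`. The default binarization for
reconstruction is INTACT → 1 (functional gene present), PSEUDOGENE and
ABSENT → 0, UNKNOWN and HOMOLOG_UNRESOLVED → `?` (uninformative). A
pseudogene is scored 0 because the character of interest is a
*functional* gene; a three-state model is deliberately not offered.

## Synteny orthology

Coordinates are 1-based inclusive internally (GFF3 convention); BED
input is shifted on read. An ortholog call finds the nearest conserved
anchors flanking the target in a reference map and asks whether the
query species has a candidate between the same anchors: one exact symbol
match → `ORTHOLOG` (evidence = 2 anchors); a name-pattern match
(default `<symbol>-like`, case-insensitive) or multiple candidates →
`HOMOLOG_UNRESOLVED`, never an arbitrary pick; an intact but empty
window → `ABSENT_FROM_WINDOW`; a missing anchor → `WINDOW_INCOMPLETE`,
which downstream maps to UNKNOWN — fragmented assemblies must not
fabricate losses. One anchor per side is required; sidedness of
neighbor queries is 5′/3′ relative to the focal gene's strand by
default (`sidedness="genomic"` restores plain left/right).

## ORF integrity and NMD

The spliced CDS is scanned in frame 0 with the standard genetic code
(configurable table id). Internal stops are `PREMATURE_STOP` lesions, a
missing initial ATG is `START_LOSS`, a missing final stop is
`TERMINAL_STOP_LOSS`. Codons containing N are recorded as ambiguous and
never become lesions; a CDS with more than 10% N should be treated as
UNKNOWN upstream rather than classified.

Frameshifts are detected against an intact reference ORF by global
pairwise alignment with match +1, mismatch −1, gap open −4, gap extend
−1 (Biopython's PairwiseAligner, first optimal alignment, which places
gaps leftmost within a repeat run). Every gap run with length ≢ 0
(mod 3) is a `FRAMESHIFT_INDEL` at the codon containing its first
aligned reference base. Because cost-equivalent gap placements slide
within repeats, a reported indel may sit up to a couple of codons
upstream of the mutational event; positions under other scoring schemes
may shift by about one codon. After indel detection the query is
re-scanned for stops in its own (shifted) frame, mapped back to
reference codons through the alignment.

NMD is predicted when a premature stop ends at least `margin`
nucleotides 5′ of the last exon–exon junction of the spliced CDS. The
default margin 0 is the literal "stop before the last exon" rule; the
canonical 50-nt boundary rule is `margin=50`. Single-exon models never
predict NMD. Functional classification: nonfunctional iff NMD is
predicted, any frameshift exists, or a premature stop truncates the rod
(intermediate-filament) domain; rod coordinates are user-supplied
annotation, and in their absence any premature stop is treated as
truncating (conservative for keratins, whose function requires the rod).
Premature stops of different species that fall in the same aligned
column of a user-supplied CDS alignment are grouped as one ancestral
lesion.

## Dollo reconstruction

Under Dollo parsimony a gene arises exactly once and is lost
irreversibly. Given a binarized leaf column, the gain edge is the edge
above the MRCA of all 1-leaves (`ROOT` when that MRCA is the root, or
when `ancestral_at_root` forces it — used for genes like *KRT24* that
are known to predate the clade covered by the matrix). Within the gain
clade a loss is placed on every *highest* edge whose subtree contains at
least one known-0 leaf and no 1-leaf; `?`-leaves impose no constraint
and never force a loss. This reconstruction is the unique minimum-loss
history, so no tie-breaking is needed; the test suite proves minimality
against exhaustive enumeration of all single-origin ancestral
labelings on every topology up to six leaves (all `{0,1,?}` columns up
to five leaves, all binary columns at six) and on seeded random
topologies at seven and eight leaves. The full exhaustive sweep at
seven-plus leaves is combinatorially out of reach of a test suite and is
replaced by sampling.

The Sankoff cross-check runs the classic two-state dynamic program with
explicit costs, charging `cost_gain` for a root labelled 1 (the gain
then sits on the stem above the root) and breaking cost ties toward
state 0. Preferring 0 delays gains to the latest cost-equivalent edge
and advances losses to the earliest one — exactly the Dollo placement —
so with a prohibitive regain cost (`cost_gain ≥ (1 + n_leaves) ·
cost_loss`) the implied events coincide with the Dollo reconstruction on
every column; the suite checks this on 1,000 fuzzed columns.

Independent-loss counting is `|loss_branches|`, optionally merging
losses whose species share an aligned lesion (the shared lesion is
evidence of a single inactivation in their common ancestor; the merged
loss moves to the edge above the group's MRCA). Events are dated to the
interval `[age(parent), age(child)]` of their edge — parsimony resolves
an event only to an edge, so no point estimates are produced. Node ages
are maximum root-to-leaf path lengths below the node; leaves have age 0.
Polytomies are allowed; losses on polytomy children are counted per
child.

## Co-evolution and heterodimers

Strict co-evolution of two genes means identical loss-branch sets. The
graded statistic is the Jaccard index of the two sets (defined 1.0 when
both are empty). Its null distribution re-places each gene's losses
uniformly at random on its eligible edges (strict descendants of its
gain, no loss nested under another; rejection sampling) and reports
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`. Both the statistic and
the null are conventions of this package for quantifying what is
otherwise a qualitative comparison, and reports label them as such.
Because the Jaccard statistic of sparse loss patterns is highly
discrete, null p-values concentrate at 1; the guarantee is validity
(super-uniformity, `P(p ≤ α) ≤ α`), not uniformity, and that is what
the tests assert. Default `n_perm` = 10,000; a seed is required.

Heterodimer tables pair each intact type I keratin with its
highest-priority intact type II partner from a ranked rule file;
keratins flagged promiscuous (K24) pair with every intact partner in
their list. Defaults ship as an editable TSV: K14→K5, K12→K3,
K10→K1 (fallback K2), K24→K3 (fallbacks K4, K5).

## qPCR model

Starting template is proportional to `E^(−Ct)` with per-gene efficiency
`E ∈ [1, 2]`; the target/reference ratio in one sample is
`E_t^(−Ct_t) / E_r^(−Ct_r)`, the ΔCt model when E = 2. Efficiencies
default to 2.0 (perfect doubling) because measured efficiencies are
rarely reported with published Ct data; this is an explicit assumption.
Per-gene values are rescaled so the maximum sample equals 10 a.u.
(idempotent and ratio-preserving). Group comparison uses the two-tailed
Mann-Whitney U test: exact null by full enumeration (scipy) when the
pooled sample has ≤ 20 untied observations — verified against an
independent enumeration oracle for all group sizes ≤ 6 and at (8, 5),
the cornea/epidermis design the package's examples emulate — otherwise
the normal approximation with midrank tie and continuity corrections.
Tied data never use the exact path.

## Synthetic data

The simulator defines the study conditions for all stochastic tests.

* **Dollo process**: gene present from the gain edge down; loss on an
  edge of length t with probability `1 − exp(−λt)`; once lost, stays
  lost. Default illustration rate λ = 0.004 per MY per lineage, chosen
  so the expected number of losses on the packaged mammal tree is of
  order 3 — the regime the real *KRT24* history sits in. Leaves outside
  the gain clade are ABSENT. By construction the simulator never plants
  nested losses (an edge can only lose what its parent still has), but
  losses on sibling edges can jointly empty a clade, in which case
  parsimony correctly merges them onto the stem; exact recovery of the
  planted branches is therefore guaranteed (and tested) exactly when
  every planted loss is a maximal lost subtree.
* **CDS mutator**: plants premature stops (substitution to a random
  stop codon), frameshifts (±k nt, k ≢ 0 mod 3) and start losses at
  requested codons, shifting exon junctions with indels; ground truth
  records exact positions. Intact templates are 300 codons by default —
  about keratin-sized.
* **Locus shuffler**: drop/insert/invert edit scripts over a gene
  order, with deterministic coordinate re-spacing; inversions flip
  strand and order, which the window extractor must (and does) undo.
* **qPCR tables**: `Ct_target = base − log2(fold) + N(0, sd)`,
  reference Ct constant plus the same noise, E = 2; defaults follow the
  emulated design of eight cornea vs five epidermis samples with
  0.5-cycle noise.

All randomness derives from one integer seed through named
`SeedSequence` streams, so adding a generator never perturbs existing
draws and identical specs give identical outputs.

Packaged fixtures transcribe only species whose states are explicitly
reported in the underlying comparative study; unstated cells are
UNKNOWN, not guessed, and each fixture file header says what its cells
encode. The fixture tree's topology follows the stated clade
relationships (cetaceans sister to the hippopotamus; Otaroidea = eared
seals + walrus within pinnipeds; *Camelus* sister to the alpaca); its
branch lengths are approximate MY values for dating illustration only.
The synthetic generators emulate presence patterns, lesion spectra and
Ct behaviour, not sequence evolution, assembly artifacts, or primer
chemistry — passing tests certify the inference machinery, not the
upstream genome screening, which is not reproducible at desk scale.

## Numerical and degenerate-input choices

* Empty locus files parse to empty maps; duplicate gene ids and
  duplicated anchors are hard errors; missing anchors are signals.
* A CDS whose length is not a multiple of 3 cannot be frame-scanned and
  the error directs users to reference comparison.
* `normalize_to_max` refuses all-zero input; `relative_quantity`
  refuses mismatched samples and identical target/reference genes.
* Exact Mann-Whitney enumeration is capped at pooled n = 20
  (C(20, 10) ≈ 1.8·10⁵ labelings); beyond that the approximation's
  error is negligible relative to the test's discreteness.
* Dating with missing branch lengths raises a dating-unavailable error
  rather than inventing ages; zero-length edges give degenerate
  intervals.

## Problem sizes used by the checks

The end-to-end suite runs the fixture reconstructions (≤ 22 species),
exhaustive Dollo optimality to six leaves plus 100 sampled cases each at
seven and eight, 1,000 fuzzed Sankoff/Dollo columns, 1,000 lesion round
trips, Mann-Whitney enumeration to pooled n = 13, 10,000 loss-process
replicates for the `1 − exp(−λt)` calibration, and 1,000 qPCR power
replicates at the (8, 5) design. The acceptance script uses 2,000
permutations for the concordance null and 400 replicates for the
simulator recovery rates.

## Known limitations

* Orthology rests on one anchor pair and gene symbols/name patterns; it
  does not detect rearrangements that move a true ortholog out of the
  window, and it cannot resolve lineage-specific duplications (these
  are deliberately surfaced as HOMOLOG_UNRESOLVED).
* Lesion positions inherit the alignment's gap-placement convention.
* The Dollo model excludes regain and rate heterogeneity; likelihood
  gene-content models are out of scope.
* The co-evolution null assumes losses are exchangeable across eligible
  edges, ignoring branch lengths; a length-weighted null would be a
  natural extension.
* qPCR efficiencies are assumed, not estimated from standard curves.
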