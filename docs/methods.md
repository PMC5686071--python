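# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user extending the package
should know. Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Repertoire annotation

Family calls replace a database BLAST search with a deterministic best-hit
local alignment: affine gaps (first gap residue −11, each further residue
−1) over a BLOSUM62 table shipped as data, against a user-supplied
labelled reference set. Because e-value thresholds are meaningless
without database statistics, the call criterion is the *normalised score*
— raw score divided by the best reference's self-alignment score — with a
default call threshold of 0.3, low enough to accept diverged family
members and high enough to reject non-homologs; it is configurable. Ties
are broken by reference order in the input file. Rh2 and SWS2 subtypes
(Rh2A/Rh2B, SWS2A/SWS2B, SWS2Aα/SWS2Aβ) use nearest-reference assignment
with a margin rule: a subtype is reported only when its normalised score
beats the runner-up by ≥ 0.02, otherwise the subtype stays unset —
coin-flip labels are worse than honest ambiguity.

Status classification is rule-based and total: *pseudogene* if any
in-frame stop occurs strictly before the terminal codon (a stop in the
final codon position is the terminal stop); otherwise *truncated* if the
exon count falls short of the family's expected count (Exorh 5, intronless
Rh1 1, LWS 6, SWS1/SWS2/Rh2 5) or the stored CDS carries more than 100
`N`s (exactly 100 is tolerated — the rule is strict inequality);
otherwise *complete*. `N`s are counted literally in the CDS rather than
estimated from an alignment, which removes a dependence on alignment
details; the CDS is therefore required to carry its `N`s. Only complete
genes are counted in the copy-number matrix.

## Synteny blocks and event inference

A block is the 6+*n* sliding window: a run of *n* opsins plus up to three
flanking genes each side, edge-truncated at contig ends and flagged as
such. Blocks are orientation-canonicalised (a block and its
reverse-with-flipped-orientations read identically), and a species' state
is the multiset of its canonical blocks.

Branch events are drawn from a unit-cost vocabulary of five operations —
single-gene loss, opsin loss (a block whose last opsin is removed leaves
the opsin-centred universe), tandem duplication of an opsin, inversion of
a contiguous segment, and translocation of an opsin. A translocation
either parks the opsin alone on a fresh contig or lands it in an observed
child block whose flanking genes are entirely new; such a target block
must contain exactly one opsin, so a translocation never changes the total
opsin count. The minimum-cardinality explanation is found by
iterative-deepening depth-first search to depth 4 (configurable) with an
admissible lower bound (opsin-count difference; one translocation per
fresh-flank child block); deeper differences are flagged unresolved, never
guessed. Among equally short explanations the search returns the one
lexicographically first in the priority gene_loss < opsin_loss <
tandem_duplication < inversion < translocation — the vocabulary has no
principled cost differences, so the ordering is a documented reporting
convention, not a weighting.

History reconstruction on the tree is a Sankoff-style dynamic programme
whose ancestor candidates are the observed leaf states plus the
intermediate states along minimum event paths between each pair of leaf
states (i.e. single-event modifications on parsimony paths). Root and
branch ties prefer the smaller repertoire (fewest opsins, then fewest
genes), matching the copy-number convention below. The restriction to
this candidate pool keeps the programme exact relative to the pool
(certified by assignment enumeration in the tests) and mirrors how such
histories are reasoned out by hand; rearrangements that exchange genes
across the window boundary are invisible inside the block universe and can
be explained by a different single event — a known, accepted limit.

## Ancestral copy numbers and habitats

Copy numbers are reconstructed per family independently by Sankoff
parsimony over the state space 0..Nmax (default: max leaf count + 2) with
linear cost |i−j| — each gene gained or lost costs one, the literal
reading of "minimum copy-number changes"; asymmetric costs are accepted
via the cost-function argument. A branch carrying a WGD mark (taken from
the tree's `[&wgd=…]` annotation, never inferred) applies i → 2i at zero
cost before the branch's change cost. Ties prefer the smaller ancestral
count, and the full ambiguity set of every node (states attained in at
least one globally optimal labeling, from a down-/up-pass) is reported —
near-root event placements are frequently tie-ambiguous, and the point
resolution is a reporting convention on top of the honest set-valued
answer. An optional constraint pass clamps named nodes to counts implied
by independent synteny evidence and recomputes the cost.

Habitats use Fitch parsimony (bottom-up intersection/union, top-down
parent preference) and equal Sankoff with 0/1 cost, which the tests check
as an internal cross-identity. Branches are painted by their child node's
state; species with unknown state are pruned before analysis rather than
imputed.

## Tuning sites and spectral predictions

Tuning sites live in bovine-rhodopsin coordinates, assigned by global
alignment of each query to the bovine reference (alignment identity below
15% is rejected as a non-opsin). Per family, the species representative
is the gene most similar to its basal-lineage counterpart, scored by the
same aligner; sites conserved across all inputs are skipped for ancestral
reconstruction.

Ancestral residues are marginal ML states from the two-pass pruning
algorithm under an equal-exchangeability chain with empirical residue
frequencies (pseudocount 1) — an F81-style model with a closed-form
transition matrix, chosen for exactness and oracle-testability over
realism; an empirical exchange matrix can be dropped in through the same
interface. Branch lengths are the time tree's multiplied by a single
substitution rate fitted by ML across the variable site columns. Each
node reports the full posterior, the MAP residue and its probability;
per-branch labels "<from><site><to>" are emitted where parent and child
MAP residues differ, joined by "/" in ascending site order. Because
labels come from per-node marginals, weakly supported columns can yield
change-plus-reversal label pairs; the attached probabilities make such
cases visible.

Spectral predictions are additive over a shipped, provenance-tagged table
of measured shifts (only effects ≥ 5 nm are admitted): total shift = sum
of per-substitution entries, except that when every member of a declared
interaction group co-occurs, the group's combined measured value replaces
the member sum (e.g. the SWS2 A94C+W265Y pair, −32 nm, smaller in
magnitude than the −33 nm sum). Reversible entries may be used backwards
with the sign flipped. A substitution absent from the table is an error,
never a silent zero. LWS λmax follows the five-sites rule: baseline
560 nm for genotype S164/H181/Y261/T269/A292 with a vitamin-A1
chromophore, plus the tabulated shift of each deviation. The two values
the package treats as anchors are the 560 nm baseline and the ~20 nm Rh2
E122Q blue shift; all other magnitudes come from the cited mutagenesis
literature and are user-replaceable configuration.

## Comparative models (BM / OU)

Copy numbers are treated as continuous traits, as the Gaussian framework
requires. The four models are: BM (σ², root value x0; k = 2), OU(1) (one
optimum θ; k = 3), OU(2) (one optimum per habitat regime from the Fitch
painting; k = 4) and OU(3) ("ancestral habitat unknown": terminal
branches keep their habitat optimum, every internal branch and the root
take a free ancestral optimum θ_anc; k = 5).

Root policy defaults to *fixed*: the root sits at its regime's optimum,
giving covariance Cov(i,j) = σ² e^(−α(Tᵢ+Tⱼ−2t_a))(1−e^(−2α t_a))/(2α)
with t_a the root-to-MRCA depth. This makes BM the exact α → 0 limit of
every OU model, so the ladder with BM (and OU1) as nulls is properly
nested for likelihood-ratio testing. A *stationary* root (variance
σ²/(2α)) is available as an option but breaks that limit. OU(2) and
OU(3) are not nested in either direction — OU(3) frees the internal
branches but discards OU(2)'s internal painting — so the default
selection report compares that pair by AIC/BIC only and reserves LRTs for
the genuinely nested pairs; the significance rule (groups differ iff
OU(2) or OU(3) rejects BM at p ≤ 0.05) is unaffected. Boundary effects
(α = 0 on the edge, optima unidentified under the null) mean the plain
χ²(Δk) reference distribution is approximate; no boundary correction is
applied, and the type-I error measured in the acceptance suite runs
slightly above nominal, consistent with that.

Fitting profiles the optima out by generalised least squares and σ² in
closed form, leaving a one-dimensional ML search over α: a log-spaced
multi-start grid (8 points spanning roughly 0.05–30 times the inverse
tree height) that always includes the exact α = 0 BM limit — which also
guarantees logL(OU) ≥ logL(BM) numerically — followed by bounded scalar
refinement. Degenerate constant traits hit a σ² floor of 1e−12 and keep
a finite likelihood. No multiple-testing correction is applied across
families; raw p-values are reported.

## Synthetic data: what it does and does not emulate

The generators produce every input with the statistical structure the
inference assumes: birth–death trees (sampled by the general sampling
approach, so terminal branches are never zero), Poisson gain/loss copy
histories with zero absorbing and WGD branches doubling then retaining
each duplicated copy with probability r (default 0.5, reflecting that
post-WGD losses are common), symmetric-rate Markov habitats, exact
Gaussian BM/OU transitions, opsin-like coding sequences descended from
family references (with canonical residues planted at the families' key
tuning sites so injected substitutions are interpretable) and injected
premature stops and >100-N runs, and gene orders evolved by the same
five-event vocabulary the inference searches over. Every generator is
deterministic under a fixed seed (one root seed fans out to stable
per-stage substreams) and returns a truth log sufficient to score the
matching inference stage.

They deliberately do not emulate: realistic sequence evolution (no codon
models, dN/dS, indels or rate heterogeneity), genome-scale contigs,
assembly artefacts other than N-runs, gene conversion, or correlated
habitat–trait confounding. Passing tests therefore certify the
*inference machinery* — that each stage recovers what its model class can
express — not robustness to real-genome noise sources outside that class.

## Problem sizes and defaults

The shipped study sizes are chosen to exercise every code path at desk
scale: the end-to-end synthetic study uses 12 species and five families
(tree height 200 Myr, divergence 3%, 10% injected pseudogenes and
truncated genes each); the comparative-method experiments use 64-species
trees of unit height with α·height = 2 and optima separated by three
stationary standard deviations, 100 replicates for parameter recovery and
200 for the null-rejection rate; oracle certifications run on trees of up
to 6 leaves, alphabets of up to 4 residues, and synteny instances of up
to 4 events, where exhaustive enumeration is exact and fast.

## Known limitations

* Synteny inversions that straddle the window boundary are invisible
  inside the block universe and may be explained as a different single
  event.
* Near-root parsimony placements (copy numbers, habitats, synteny, and
  root-child substitution placements in ASR) are inherently tie-ambiguous;
  the package resolves them by documented conventions and reports the
  ambiguity sets.
* The OU LRT uses the plain χ² reference despite the α boundary; its
  size is approximate by construction.
* Marginal (per-node) ASR can emit jointly inconsistent label pairs on
  weak columns; joint reconstruction is not implemented.
* WGD placement is an input, never inferred; gene-conversion detection
  and probabilistic gene-family models are out of scope.
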