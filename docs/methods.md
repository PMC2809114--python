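# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the pipeline, in the order the analysis runs.

## Codon alignments

Input alignments are in-frame coding sequences (length a multiple of
three) under the standard genetic code (61 sense codons, 3 stops).
Ambiguity codes and gaps are retained in the sequence text, but any codon
containing one is treated as missing data: excluded pairwise from distance
computations, and given a flat partial likelihood in model fits.  Columns
with gaps would be dropped by complete deletion before analysis; the
bundled fixture contains none, matching the gap-free data the pipeline is
designed for.  Site numbering is 1-based by alignment codon; a configurable
integer offset maps codon indices to reference (bovine-rhodopsin-style)
residue numbers, because the mapping between an alignment fragment and the
canonical numbering is a property of the data, not of the method.  The
fixture uses offset 15, so its 278 codons span reference sites 16–293 and
the planted sites carry the familiar labels 104, 183 and 270.

## Partitioned distances (LWL85)

Each position of each sense codon is assigned a degeneracy class by
enumerating its three single-nucleotide mutants: 4-fold if all are
synonymous, 0-fold if none, 2-fold otherwise.  Three-fold positions (Ile)
are collapsed into the 2-fold class, and mutations to stop codons count as
nonsynonymous, following the original convention.  Over the 61 sense
codons this yields the fixed totals 116 / 35 / 32 positions
(0- / 2- / 4-fold), regression-tested.

For a sequence pair, site counts `L0, L2, L4` are averaged over the two
sequences; each observed difference is attributed half to each sequence's
site class, and split into transitions and transversions.  Per class the
Kimura two-parameter pieces are `A = ½ln 1/(1−2P−Q) − ¼ln 1/(1−2Q)`
(transition part) and `B = ½ln 1/(1−2Q)` (transversion part); 2-fold
transitions are synonymous and 2-fold transversions nonsynonymous, so

    Ks = (L2·A2 + L4·(A4+B4)) / (L2/3 + L4)
    Ka = (L2·B2 + L0·(A0+B0)) / (2·L2/3 + L0)

Definedness is tracked per component: `A` saturates when `1−2P−Q ≤ 0`, `B`
when `1−2Q ≤ 0`; an undefined component makes only the distances that use
it undefined (e.g. a saturated 2-fold transition correction invalidates
Ks but not Ka).  Undefined distances are NaN, reported by pair, and abort
tree building rather than being imputed.  Codons differing at more than
one position contribute each differing position independently, without
pathway averaging — the distance-based reading of the method.

Two auxiliary modes serve the tree scans: Poisson-corrected amino-acid
distances `−ln(1−p)` and plain K2P over all nucleotide columns.

## Neighbor-Joining and bootstrap

NJ is the standard Saitou–Nei agglomeration.  Ties in the Q criterion
(within 1e−12) are broken by the lexicographically smallest pair of
cluster keys (a cluster is keyed by its smallest taxon label), making the
tree deterministic.  A negative branch-length estimate is clamped to zero
with the deficit moved to its sister branch, preserving path lengths.
Bootstrap resampling draws codon columns with replacement (for amino-acid
distances a residue column coincides with a codon column); support is the
percentage of replicate trees containing each full-data split; replicates
with undefined distances are dropped and more than 10% dropped is an
error.

One consequence of deterministic tie-breaking worth knowing: on data with
many zero distances (e.g. nonsynonymous distances after removing the only
informative site) the arbitrary-but-deterministic join order can produce
clades that look meaningful but carry no signal.  Bootstrap support — which
perturbs the ties — is the honest summary in that regime.

## Codon models

The GY94 rate matrix has `q_ij = π_j · κ^[transition] · ω^[nonsynonymous]`
for single-nucleotide codon changes, zero otherwise, scaled to one
expected substitution per codon site per unit branch length.  Codon
frequencies are F3x4 (positional nucleotide frequencies, renormalised over
sense codons) estimated from the data.  States with zero frequency are
excluded from the support; transition probabilities come from the
symmetrised eigendecomposition, with per-node rescaling in the pruning
recursion.  Likelihoods are computed over unique site patterns.

Implemented models: M0; two-ratio (foreground branches named by clade leaf
sets or node labels, with an optional `ω_fg = 1` null); free-ratio; M1a
(`0<ω0<1`, `ω1=1`); M2a (adds `ω2≥1`); M8 (β(p,q) discretised into 10
equal-probability categories by mid-quantiles, plus an `ωs≥1` class) and
its M8a null (`ωs=1`); branch-site model A and its `ω2=1` null, with the
codeml class structure (0, 1, 2a, 2b).  Bounds: ω ≤ 50, κ ∈ [0.01, 100],
branch lengths ∈ [1e−8, 20], proportions in (1e−6, 1−1e−6).

Fitting optimises branch lengths and model parameters jointly (log/bounded
transforms, L-BFGS-B, ftol 1e−10) from multiple seeded starts: a
deterministic heuristic start, optional warm start from a nested fit, and
seeded perturbations.  The best objective value seen — including the start
points themselves — is kept, which guarantees `lnL(alt) ≥ lnL(null)` when
the alternative is warm-started from the null.  Parameter counts include
branch lengths (one per edge of the derooted tree), so nested-model
degrees of freedom match the conventional values (M1a vs M2a: 2, M8a vs
M8: 1, branch-site test 2: 1).  LRTs use the χ² upper tail with df equal
to the parameter difference and the statistic clamped at zero.

Site posteriors are **naive** empirical Bayes: per-class site likelihoods
at the fitted parameters, weighted by the fitted proportions and
normalised.  This deliberately omits the parameter-uncertainty integration
of Bayes empirical Bayes; posteriors for weakly-occupied classes are
correspondingly optimistic point estimates.

Trees are derooted for fitting (a bifurcating root's two edge lengths are
not separately identifiable under a reversible model); the fitted length
of the merged edge is split equally when mapped back to a rooted tree.

## Ancestral reconstruction

Marginal reconstruction runs under the fitted M0 model only (the study
design: one ω for reconstruction, mixtures for selection tests).  The
standard inside–outside recursion gives, at each node and site, a
posterior over codons proportional to the product of the partial
likelihoods of all incident subtrees weighted by π; the MAP codon is the
reconstructed state.  Because the model is reversible and π stationary,
posteriors at named internal nodes are independent of root placement
(tested); the root node itself is the one position-dependent exception.

**Polarity ambiguity.** Without an outgroup, a replacement shared by two
clades on opposite sides of the root admits two equally-parsimonious
histories: two independent gains, or presence at the root with two
independent losses.  The likelihood tie is broken by branch lengths, so
the census can report a planted S→G pair as the mirror-image G→S pair on
the complementary branches.  The site and the amino-acid pair are always
correct; the arrow may flip.  Tests therefore assert site identity and
grouping, not polarity.

## Convergence census

Events are net per-branch codon differences between MAP parent and child
sequences; a codon differing at several positions is one event, classified
synonymous/nonsynonymous by the amino-acid pair (pathway decomposition is
unidentifiable and not attempted).  Shared replacements group events by
(site, derived amino acid); a group is kept when its branches are pairwise
disjoint (neither ancestral to the other — sister branches allowed),
enforced greedily from the largest clade down; it is *parallel* when all
ancestral residues agree and *convergent* otherwise.  Reversals are
site-level patterns a→b on an outer branch undone b→a strictly inside its
subtree.  Domain mapping uses an editable YAML table of
transmembrane/intradiscal/cytoplasmic intervals; the bundled table is an
approximate bovine-rhodopsin topology with round-number boundaries, so
domain tallies are fixture-anchored, not literature values.

## Site-exclusion scans

For each configured set of codon sites the scan drops those columns,
rebuilds the NJ tree in the requested mode, and reports the RF distance to
a reference tree plus named clade checks.  On the fixture, excluding the
fruit-bat/tomb-bat site dissolves the false nonsynonymous-tree clade and
the nucleotide tree without the site is species-tree concordant; excluding
any other site leaves the conflict in place.

A structural note: with NJ on all-nucleotide K2P distances, one codon can
contribute at most three columns, so a single convergent site can only
flip the tree when the competing true internal edge carries at most ~2
synonymous changes.  An edge that weak cannot simultaneously be recovered
reliably by the synonymous-site tree.  The fixture therefore expresses the
baseline conflict in the nonsynonymous partition (where background
divergence is near zero and the planted columns dominate), and the
nucleotide-mode scan demonstrates concordance once the site is removed —
the two halves of the published contrast that are jointly attainable at
these study conditions.

## The synthetic fixture

`bat_fixture(seed)` emulates the study data: 23 taxa named by clade
(5 Pteropodidae, 5 Rhinolophoidea, 1 tomb bat, 3 Miniopterus, 9 other
Yangochiroptera; real taxon identities are not part of the fixture),
278 codons (834 bp), κ = 3, ω = 0.03, uniform codon frequencies, on the
accepted species phylogeny (Miniopterus inside Yangochiroptera; tomb bat
an early Yangochiroptera lineage).  Branch lengths are 0.015 (terminal)
and 0.035 (internal) substitutions per codon: each internal edge then
carries ~8 synonymous changes, enough for NJ to resolve every edge
reliably, at the cost of somewhat more realized variability (~200 variable
nucleotide columns) than the real alignment's 147 — resolvability was
preferred over exact variability matching.  Simulation is exact
(event-by-event exponential waiting times), so the complete substitution
history is recorded; replaying it from the root reproduces every sequence,
and a realized-count estimate of dN/dS at spec ω = 0.1 falls in
[0.07, 0.13] over 50 000 codon-branch draws.

Plantings force a derived codon at the end of a branch and re-simulate the
site downstream.  The fixture plants S→G uniting the fruit-bat stem and
the tomb bat (TCT→GGT), and V→I (GTA→ATA) and M→L (ATG→CTG) uniting the
Miniopterus and Rhinolophoidea stems.  Codon pairs were chosen so that
every differing column falls in a nonsynonymous site class: the planted
signal appears in Ka, amino-acid and nucleotide distances but leaves Ks
untouched, exactly the partition contrast the analysis is about.  The
S→G pair differs at two positions (a deliberate multi-column footprint;
a single-column replacement carries the same amino-acid signal but a
weaker distance signal).

What the fixture does **not** emulate: real codon usage (uniform π),
among-site rate variation, CpG and context effects, alignment error,
outgroups, and the real taxon sampling of the study (whose exact sequence
set is not reproducible offline).  Passing tests certify the machinery
and the planted-signal logic, not agreement with the published estimates
from the real alignment.

## Problem sizes in the test suite

The acceptance tests run the oracle comparisons at 100 random pairs
(distances) and all topologies with ≤ 3 internal nodes (likelihood,
exhaustive 61^k enumeration); parameter recovery at 8 taxa × 1000 codons;
the fixture experiments at 20 seeds; ancestral accuracy at 3 × (8 taxa ×
300 codons); and the M1a/M2a type-I experiment at 20 replicates of
6 taxa × 200 codons with warm-started alternatives.  These sizes were
chosen as the smallest at which the respective properties are
statistically unambiguous.
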