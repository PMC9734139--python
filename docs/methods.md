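# Methods

This note documents the models and procedures the package implements, the
choices made where the published descriptions of such analyses leave the
design open, and what the synthetic-data validation does and does not
establish.

## Phylogeny and the focal/background partition

All scans operate on a rooted species tree with branch lengths in expected
substitutions per site. A *focal clade* (a tip set verified monophyletic
at load time) is contrasted against all remaining tips (*background*);
the *sister lineage* is the tip set of the other child of the focal MRCA's
parent and is derived automatically from the topology, never supplied by
hand. Coordinates are 1-based and closed throughout; residue *i* of a
coding gene maps to nucleotide 3(*i*−1)+1, so residues 208/207 map to
622/619.

## Ancestral reconstruction

Marginal posteriors P(node = a | column) are computed by the up–down
(inside–outside) form of the pruning algorithm under a reversible model
Q_ij = s_ij π_j, scaled to one expected substitution per unit branch
length. The default protein model is Poisson+F: uniform exchangeabilities
with frequencies estimated from the alignment (add-one pseudocount);
nucleotide reconstruction uses Jukes–Cantor. Reasons for this choice: the
downstream 0.95 posterior threshold is robust to the exchangeability
matrix for the clade-invariant site patterns it gates, and Poisson+F is
fully reproducible with no external rate tables. Branch lengths are taken
from the input tree as-is.

Numerics: P(t) = exp(Qt) via symmetric eigendecomposition of
D^{1/2} Q D^{−1/2}, cached per distinct branch length, clipped to [0,1]
and renormalised row-wise; partial likelihoods are max-rescaled per node
and site with accumulated log-scalers. Gaps are missing data (all-ones
partials), never an extra state; an all-gap column contributes zero
log-likelihood and its MAP state is reported as `-` with an `unsupported`
flag. MAP ties break to the alphabetically first state.

Limits worth knowing: there is no among-site rate heterogeneity and no
joint (as opposed to marginal) reconstruction. MAP root-state recovery on
simulated data is bounded by an irreducible error: a substitution on
either root-adjacent branch leaves the two single-change explanations of
the column nearly equally likely (the reversible model cannot tell them
apart), so roughly half of such sites are misassigned no matter the
implementation. Measured on 2,000-site simulations along the bundled tree:
99.4–99.8% recovery at uniform branch length 0.005, ~98.7% at 0.01,
~97.5% at the bundled lengths (height ≈ 0.13). The test suite asserts the
corresponding floors rather than a height-independent constant.

## Lineage-specific mutated sites

A candidate column requires strict invariance on both sides: all focal
tips share residue X, all background tips share residue Y ≠ X; any gap or
polymorphism on either side disqualifies the column (the strictest reading
of "all other background species"; whether real analyses would tolerate
background polymorphism is left as an explicit non-option). Two filters
follow:

* **Ancestral support.** P(focal MRCA = X) ≥ 0.95 and
  P(MRCA's parent = Y) ≥ 0.95 — the minimal node pair certifying that the
  substitution occurred on the focal stem. If the focal MRCA is the root,
  the parent check falls back to requiring the support of Y at every
  root child outside the focal clade (logged). The threshold is inclusive
  (exactly 0.95 passes).
* **Alignment quality.** Over the even window [c−4, c+5] (truncated at
  alignment ends, not padded), pairwise similarity per taxon pair is
  identical residues over columns ungapped in both sequences — the
  denominator deliberately excludes shared indels so they are not punished
  as mismatches; a pair with no comparable column scores 0 with a warning.
  mean < 0.7 or min < 0.35 rejects (strict inequalities, so the printed
  boundary values are retained). Similarity is computed over all taxa,
  focal included.

## Branch rates and the rapid-evolution decision

Per-branch dN uses NG86 counting between the sequences at a branch's two
endpoints: tips contribute their observed codon sequences, internal nodes
their MAP ancestral nucleotide sequences. Site counts per codon are the
fractions of the nine point changes that are synonymous (changes to stop
codons count as nonsynonymous); differences are averaged over all shortest
substitution paths with stop-visiting paths excluded and the remainder
reweighted equally; proportions are Jukes–Cantor corrected,
d = −(3/4)ln(1 − 4p/3), flagged *saturated* (and treated as missing) at
p ≥ 3/4. This NG86-on-MAP-ancestors engine is an explicit surrogate for a
maximum-likelihood free-ratio fit, which the package intentionally does
not re-implement; externally fitted branch dN tables load through the same
interface (`read_branch_dn_tables`) so the decision layer can run on
either source.

The decision statistic treats the focal stem's dN as a new observation
against the background branches (all branches except the focal stem; at
least three non-missing values required):

    t = (dN_focal − mean(dN_bg)) / (s_bg · sqrt(1 + 1/n)),  df = n − 1,

two-sided. This "prediction" form is calibrated: under branch
exchangeability its null rejection rate equals the nominal level (measured
0.046–0.058 at α = 0.05 over 500-gene null simulations). The naive
one-sample form that plugs the focal dN in as a hypothesised population
mean is also available (`method="popmean"`) but is strongly
anticonservative (~0.70 measured null rejection at α = 0.05), because the
focal value is itself a random draw whose variance the statistic ignores;
it is provided only for comparison with pipelines that used it. P-values
are BH-adjusted across genes and a gene is flagged only when additionally
dN_focal > dN_sister — with "the focal lineage's dN" read as the stem
branch (a clade-average variant would be a one-line change and is not
offered to keep the decision unambiguous). Degenerate zero-variance
backgrounds yield p ∈ {0, 1} with a warning.

The positive-selection layer only converts branch-site model
log-likelihood pairs into decisions: 2(ln L₁ − ln L₀) referred to χ²(1)
(no 50:50 mixture), negative statistics within 1e-6 clamped to zero,
larger ones rejected as non-converged fits; BH across genes at 0.05.

## Gene loss and character mapping

Loss calling is a deterministic rule: copy number 0 in every focal
species and ≥ 1 in *at least one* sister species ("present in the closest
sister lineage" names the lineage, not each member; a strict all-sister
variant is a flag). Families with zero counts everywhere are unobservable
and excluded with a warning.

Binary characters are mapped by minimum-change parsimony in Hartigan's
counting form, which is exact on multifurcating trees; `?` enters as the
full {0,1} ambiguity set. The top-down pass keeps the parent's state
whenever it is in the child's optimal set, i.e. changes are placed as
tipward as the optimum allows (DELTRAN-flavoured); the change count — the
quantity all conclusions rest on — is placement-independent and is
verified against exhaustive search. An implementation assertion checks
that the realised placement attains the optimal count on every call.

## Annotation weighting and enrichment

The single-function rule uses a strict inequality on the share of *all*
members (annotated or not) whose annotation term sets are identical:
10/11 (> 90%) collapses to weight 1, 9/10 (= 90%) does not. In the
fractional branch, every annotation instance counts separately (a member
annotated twice with the same term contributes two instances). Weights
always sum to 1 per family.

Because fractional weights break the integer assumptions of the
hypergeometric test, term enrichment in a family set uses a seeded
permutation test on weighted term sums: null foregrounds are equal-size
uniform draws, p = (1 + #{null ≥ observed}) / (1 + n_perm) with ties
counted as exceedances (a 1e-9 epsilon absorbs summation-order rounding).
P-values are therefore conservative and bounded below by 1/(n_perm+1);
BH is applied across terms. Exactness of the null was validated as
uniformity of an unplanted term's p-value across independent replicates —
a cross-*term* uniformity check is not meaningful on sparse annotation
matrices, where many terms tie at observed weight 0.

## Genome size

Size = K_num / K_depth on the retained part of the depth histogram.
The error spike is excised at the first local minimum (first depth where
counts rise again after the initial descent); a histogram that never
descends needs no cutoff, one that descends without rising again requires
an explicit cutoff. K_num sums depth × count (occurrences, not distinct
k-mers — dividing occurrences by depth is what yields a length in bp);
K_depth is the modal retained depth, smallest depth on ties. Heterozygous
peak folding is not modelled. Note an inherent granularity: K_depth is an
integer, so the estimate carries a relative bias of (λ − ⌊λ⌋)/⌊λ⌋ at
non-integer mean coverage λ and a mode-tie artefact at integer λ; both
shrink with coverage (< 2% for λ ≥ 30, < 3.5% at λ = 30 worst case).

## Synthetic data

The generators emulate the study setting on a fixed 13-taxon tree (four
focal tips, a three-tip sister clade, six backgrounds, height ≈ 0.13);
all randomness flows from one integer seed and every dataset ships with a
truth table. Protein alignments evolve site-independently under the
reconstruction model itself; a planted lineage-specific substitution is
imposed by freezing the site (focal tips = derived residue, background
tips = ancestral), and window corruption replaces listed cells with random
residues at a given intensity — literal within-column shuffling cannot
degrade a conserved window, so replacement is what the quality filter is
exercised against. Codon alignments evolve by per-codon Gillespie
simulation of an MG-style process (synonymous neighbour rate 1/3,
nonsynonymous ω/3, stop codons inaccessible, default ω = 0.5), with the
focal-stem nonsynonymous rate multiplied by the configured shift; branch
lengths default to a uniform 0.05 so branches are exchangeable under the
null, which is what makes the calibration measurement meaningful.
Orthogroup matrices draw Poisson(1.5) copy numbers with planted losses
zeroed in the focal clade (and a guaranteed sister copy), and non-loss
families guaranteed one focal copy so recovery is exact by construction.
Histograms draw Poisson coverage per k-mer plus a depth-1 error spike of
0.2 × genome-size k-mers.

What passing these simulations does *not* show: robustness to alignment
error beyond the modelled window corruption, to model misspecification
(the simulator and the reconstruction share the substitution model), to
indel evolution (gaps are only planted, never evolved), or to
heterozygosity in the k-mer spectrum. Problem sizes in the test and
acceptance runs (50 planted genes of 260 columns; 500 null and 100
shifted codon genes of 300 codons; 1 Mb simulated genomes) were chosen as
the smallest at which the binomial noise of the measured rates is well
inside the asserted margins.
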