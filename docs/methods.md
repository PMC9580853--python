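# Methods

## Residue interaction network

A structure is parsed from PDB text (strict parsing; alternate locations
resolved to the highest-occupancy conformer, ties to the first listed;
insertion codes kept in the residue key; waters and non-standard
residues dropped). Author numbering is never re-indexed, because
clinical variant tables are keyed by HGVS mature-protein numbering.

Contacts use a heavy-atom distance criterion: residues *i, j* interact
if any heavy-atom pair is within the cutoff (default **5.0 Å**) and
|number(i) − number(j)| ≥ **2** on the same chain (covalently adjacent
residues would contribute uninformative edges; residues distinguished
only by insertion codes fall back to their ordinal distance). One typed
edge is emitted per (pair, contact class), the class being
main-chain/main-chain, side-chain/main-chain or side-chain/side-chain
according to the atoms achieving contact. Hydrogen bonds are detected
from heavy-atom geometry alone — donor–acceptor distance ≤ **3.5 Å**
and antecedent–donor–acceptor angle ≥ **120°**, with donors/acceptors
from per-residue chemistry tables — which avoids a protonation-placement
dependency. The simplified graph collapses all typed edges between a
pair into one undirected edge; by default the node set is exactly the
residues participating in ≥ 1 contact (isolated residues are not
nodes). Probe-rolling contact detection (as performed by some dedicated
contact-surface tools) is not reproduced; the distance criterion is the package's
default and is recorded, with all parameters, in the graph metadata.

## Centrality panel

Degree; unnormalized shortest-path betweenness (equal-length paths split
evenly); closeness with the Wasserman–Faust per-component scaling;
PageRank (damping 0.85, convergence tolerance 1e-12 so results are
reproducible to ~1e-9); HITS authority computed per connected component
(the principal eigenvector is unique there; on an undirected graph
authority equals hub score, so it is computed once); and Burt's
constraint with proportional tie strengths p_ij = 1/degree(i) and no
self-weight term, matching the standard closed forms (star center 1/n,
triangle 9/8). Isolated nodes get a missing constraint.

Percentiles follow the "percentage of other residues with a strictly
smaller value" convention: 100·#{u ≠ v : x_u < x_v}/(n−1). Values equal
to within 1e-9 (relative) count as ties, so iteratively computed
measures keep symmetric nodes at one percentile. Spearman correlations
between measures use average ranks for ties; pairs with fewer than three
complete observations, or a constant column, yield a missing entry.

## Structural measures

areaSAS is computed by rolling-probe surface sampling (probe **1.4 Å**,
300 sphere points per atom by default, 1000 where tests need tighter
reproducibility) with element-based van der Waals radii, so toy
structures with partial side chains are handled. A true solvent-excluded
surface is not computed: **areaSES defaults to the SASA value**, and a
plug-in backend hook accepts an exact SES implementation. Every
downstream consumer uses either the Gly-X-Gly ratio or the buried flag,
both rank-driven, which is why the approximation is acceptable; the
choice is recorded in the output metadata. Because the sphere-point
sampling is fixed in space, SASA is exactly translation invariant but
only rotation invariant up to sampling error (~1% at 1000 points); the
tests assert accordingly.

Relative exposure divides a residue's area by the reference area of the
same residue type in an extended Gly-X-Gly tripeptide (bundled
theoretical maximum-ASA table; overridable). The buried call divides
relative exposure by its maximum over the structure and applies a
strict < **0.25** threshold. The division order (Gly-X-Gly ratio first,
then normalization by the structure maximum) is a package choice where
the convention was ambiguous.

Backbone φ/ψ use the IUPAC sign convention and are missing at chain
termini or where backbone atoms are absent. The fallback
secondary-structure assigner is a coarse Ramachandran box rule — helix
for φ ∈ [−100, −30] ∧ ψ ∈ [−80, −5], strand for φ ∈ [−180, −45] ∧
(ψ ≥ 90 ∨ ψ ≤ −160), otherwise coil; it never produces turns and is
only used when no external (STRIDE/DSSP-style) table is attached.

## Critical residues

Groups are assigned from percentiles with defaults **high = 80th**,
**low = 30th** (HDHB: both ≥ high; LDHB: degree ≤ low ∧ betweenness ≥
high; LDLB: both ≤ low); the thresholds were chosen to be consistent
with the observed percentile ranges of published group memberships, are
exposed as flags, and are embedded in every output. Link nodes are
residues with at least one contact whose endpoints carry different
domain labels. The supercritical set is the weak-Pareto front over
(degree ↑, betweenness ↑, constraint ↓): a residue is dominated if some
other residue is at least as good on all three criteria and strictly
better on one; exact ties on all three are both kept. Group contrasts
use the unpaired two-sided Wilcoxon rank-sum (Mann–Whitney) test with
tie correction; scipy's exact method for small tie-free samples, normal
approximation otherwise.

## Amino-acid distance index

The property matrix (rows = numeric properties, columns = the 20
standard amino acids in the fixed order ACDEFGHIKLMNPQRSTVWY) is loaded
from TSV or obtained at run time from R's seqinr package, which ships
the 544-property collection. Properties with any missing amino-acid
entry are dropped (no imputation; the count is logged). Properties are
**standardized** (zero mean, unit variance across the 20 amino acids;
zero-variance properties dropped) before PCA — without standardization
the variance target is dominated by a few large-scale properties and the
component count collapses (10 instead of 18 on the 544-property
collection at 99%), so the standardized convention is the package
default; the flag is configurable and recorded. The smallest component
count whose cumulative explained variance reaches the target (default
**0.99**) is kept, and the 20×20 Euclidean distance matrix between
amino-acid score vectors is the distance index (symmetric, zero
diagonal, triangle inequality — asserted in tests; rotation-invariant in
component space).

## Severity classification

Sanitation keeps missense records inside the activated protein (light
chain 47–191, heavy chain 227–461), maps mild and moderate onto one
`mild_moderate` class, and drops — each with a logged reason code —
positions in the signal/propeptide or activation peptide (192–226),
ambiguous severity strings spanning two classes ("mild/moderate",
"moderate/severe"), unparseable severities, synonymous records and
non-standard residues.

Feature rows combine the wild-type position's structural measures and
centrality panel, the 1–9 conservation grade, the substitution distance
d(wt, mut) from the index, and any external predictor columns carried
as opaque numerics. Rows with any missing value are removed. Features
are min-max normalized to [0, 1] **globally over the retained rows**
(the protocol-faithful convention); the constants are frozen in the
assembler and re-applied (with clipping) to prediction-time rows such as
saturation mutagenesis. Conservation uses the ConSurf-style 1–9 scale
with 9 = most conserved; source descriptions of the scale's polarity
disagree, and the package treats the 1–9/9-most-conserved convention as
canonical.

The protocol is repeated stratified k-fold CV (defaults **10
repetitions × 10 folds**; repetition r uses base_seed + r): per outer
fold, each of the six algorithms is tuned by an inner stratified
grid search (default **10-fold**, criterion accuracy, grid-order ties to
the first best point) and predicts the held-out fold, giving each
instance exactly one out-of-fold probability per algorithm per
repetition. Metrics: accuracy, Cohen's kappa, MCC, and AUC (rank
statistic; severe = positive class; undefined for single-class folds).

Search lattices sit inside the documented intervals (grids are validated
against them): DT min-split {2, 10, 25, 50} ⊂ [2, 50], min-leaf
{1, 5, 15, 35} ⊂ [1, 35], complexity {1e-4, 1e-3, 1e-2, 0.1, 1}; RF
trees {4, 50, 100} ⊂ [4, 100], mtry {2, 4, 7} (capped at the feature
count), leaf {1, 3, 5}; SVM radial γ {0.01, 0.1, 0.3, 0.5, 1.0, 1.5};
SVM polynomial c {0, 1, 2}, d {2, 3, 4, 5}; XGBoost depth {1, 3, 10,
25} ⊂ [1, 25], learning rate {0.01, 0.1, 0.3, 0.5}. Two substitutions
were necessary for the continuous-feature setting: Gaussian naive Bayes
is smoothed via `var_smoothing` (Laplace smoothing applies to
categorical NB), and SVM probabilities come from sigmoid calibration
(CalibratedClassifierCV, 3-fold, single calibrated model) since direct
probability support is deprecated in current scikit-learn.

The ensemble search evaluates **all 2⁶ − 1 subsets** by the
per-instance median of member probabilities, scored by accuracy at
threshold 0.5 on the pooled out-of-fold predictions (criterion
selectable: AUC, MCC); ties prefer smaller subsets, then lexicographic
order. The fitted ensemble's median P(severe) is the Severity Score;
calls are severe at score ≥ 0.5, and the exclusion zone abstains where
|score − 0.5| < margin. The trade-off curve evaluates margins 0.00–0.45
in steps of 0.05: retained fraction is non-increasing by construction
and accuracy is computed over retained instances only. Saturation
mutagenesis scores all 19 substitutions per position, aggregates
per-residue means, and contrasts buried vs exposed sites with the
rank-sum test.

## Synthetic data generator

The generator emulates the statistical structure of curated clinical
mutation tables, not protein biophysics. A toy structure ("globule":
compact lattice arrangement with locally planted backbone atoms; also
ideal helix/strand/two-domain builders with Engh–Huber geometry, NeRF
chain construction, φ/ψ exactly recoverable) provides real computed
burial and centrality values. Per sampled (position, mutant) pair a
latent score

    z = w_b·buried + w_d·degree_pct/100 + w_c·conservation/9
        + w_a·aa_distance_norm + Normal(0, σ)

is drawn and the labels severe/mild_moderate split at the
balance-matching quantile. Defaults — n = 400 mutations, class balance
213:180, weights (1, 1, 1, 0.5), σ = 0.3 — put comparable effect mass
on burial, centrality and conservation with a smaller substitution-size
term and enough noise that single models stay clearly below perfect
accuracy; the conservation table is sampled with a mild tilt toward
buried residues being conserved. Everything is deterministic per seed.

What passing recovery tests show: the pipeline can extract a planted
monotone signal of exactly the kind reported for real structures. What
they do not show: performance on real clinical data, whose labels are
noisier, whose features are correlated in ways the generator does not
model (toy structures lack full side chains, real conservation is
phylogenetic, external predictor columns are absent), and whose curated
scale is fixed. Accuracy figures on synthetic data are therefore
properties of the machinery, not clinical claims.

## Problem sizes and numerical choices

The test suite and the acceptance script run the protocol at reduced
size — typically 1–2 repetitions, 10 outer folds, 3 inner folds on the
n = 400 synthetic set; the permutation-null check uses n = 150 with the
two fastest algorithm families and 10 permutations — which keeps the
full suite at a few minutes while exercising every code path; the
package defaults remain 10×10×10. Other numerics: percentile tie
tolerance 1e-9; PageRank tolerance 1e-12; SASA sphere points 300
(default) / 1000 (tests); degenerate normalization columns map to 0
with a warning; empty abstention sets yield missing accuracy.

## Known limitations

- areaSES is an approximation (see above); plug in an exact SES backend
  for absolute SES values.
- The fallback secondary-structure rule distinguishes only H/E/C and
  should be replaced by an external assignment table when available.
- Authority scores on graphs with several similar-sized components
  depend on the per-component normalization convention (documented
  above).
- The probe-rolling contact definition is not implemented; edge counts
  on real structures will differ somewhat from probe-based tools.
- External predictor columns (SIFT/PROVEAN/PolyPhen-2 style) are
  consumed as opaque numeric features; the package never recomputes
  them.
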