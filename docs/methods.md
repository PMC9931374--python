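# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Probabilistic quantization

Continuous omics measurements are treated as noisy read-outs of a trinary
hidden state x in {-1, 0, +1}. Each value is mapped to its within-feature
mid-rank CDF value u and then to a posterior vector through two logistic
ramps:

    p(+1) = sigmoid(s (u - q_high)),   p(-1) = sigmoid(s (q_low - u)),

with p(0) the remainder (clipped and renormalized). The mapping depends on
the data only through ranks, so monotone transforms of the raw scale leave
the output unchanged; missing values map to the uninformative (1/3, 1/3,
1/3).

**Cut points.** The defaults are the tertiles q_low = 1/3, q_high = 2/3
with slope s = 20. Tertile cuts make the three states a priori
equiprobable, which matches the uniform trinary null of the association
model; cut points far in the tails (e.g. 0.15/0.85) systematically starve
the +/-1 states of posterior mass when states are in fact near
equiprobable, which attenuates every downstream log-likelihood ratio and
fitted weight. The exact functional form of the quantizer is a documented
stand-in — any monotone map of u with the same interface can be swapped
in. CNV layers re-fit the cut points per feature to the empirical fraction
of amplification/deletion calls (values beyond +-0.3 on the raw
copy-number scale by default), so sparse alteration layers are not forced
into the equiprobable prior.

Mutation codes (0/1/2 = silent/missense/nonsense) and SNP genotypes
(minor-allele counts) are represented with all probability mass on the
reported code. CNV probes merge into segments while the mean per-sample
L1 distance between a probe's posterior and the running segment average
stays within 0.1 (configurable).

## Association models

The conditional law p(y|x) = exp(sum_i lambda_i f_i(x_i) y)/Z with
lambda_i >= 0 is fit by maximizing the *expected* log-likelihood under the
quantization posteriors. With k <= 6 effectors the expectation over joint
effector states is enumerated exactly; the sufficient statistics
(a_g = sum_s P_s(g) E[y_s], b_g = sum_s P_s(g) per joint state g) are
precomputed once, so the optimization cost is independent of the sample
count. Beyond 6 effectors a mean-field plug-in of expected feature values
is used. The objective is concave in lambda; one-effector fits use a
safeguarded Newton iteration on [0, inf), larger fits L-BFGS-B with an
analytic gradient (gradient tolerance 1e-6, 500 iterations, non-converged
fits flagged, never raised).

Feature functions: trinary state value for CNV/methylation/miRNA/
phosphoprotein effectors, non-silent indicator (code >= 1) for mutations,
allele dosage (genotype - 1) for SNPs; the association direction flips the
sign. Types with a fixed module-level direction (cis-CNV +, methylation -,
miRNA -) are fit in that direction only; for other types both directions
are tried and the better likelihood kept.

**Testing.** The LLR against the uniform null is referred to a 50:50
mixture of a point mass at zero and chi-square(1) when a single fixed
direction was fit (the nonnegativity constraint makes the null a boundary
case); when both directions were tried, the maximum over the two signed
fits is asymptotically two-sided and the plain chi-square(1) tail is used.
For df > 1 nested tests the plain chi-square(df) tail is used. With soft
posteriors the expected-likelihood LLR is mildly conservative relative to
these references (the information identity holds exactly only for
point-mass states); the permutation test — refitting with the added
effector columns independently permuted, p = (k+1)/(B+1) — is the
calibrated safeguard and is required alongside the asymptotic test in
model selection.

**Screen calibration.** The pairwise-screen threshold is the smallest t
with estimated FDR(t) = ((permuted count >= t) + 1)/B / (observed count
>= t) at most the target. The add-one smoothing keeps the estimate away
from an unstable zero in the extreme tail; without it the single largest
observed statistic is declared a discovery under the global null about
half the time.

**Stepwise selection.** Candidates passing the screen are ranked by
unweighted shortest-path distance from their network anchor to the target
(cis-CNV anchored at its overlapped gene, distance 0 for the target's own
locus), ties broken by type (CNV > mutation > methylation > miRNA >
phosphorylation > SNP) and then pairwise LLR. A candidate is accepted only
when the augmented model beats both the current model and the
candidate-alone model with chi-square AND permutation p at most alpha
(default 0.05, 200 permutations in the selection loop, cap of 20
effectors). Permutations are skipped — and the candidate rejected — when
the asymptotic test already fails.

## Modules, Super Modules, Sample Groups

Association Modules collect the targets sharing one (effector, direction)
pair; the realizable grid has 11 classes. The default minimum module size
is 5 targets. Trans-CNV and SNP modules must carry a regulator: a gene at
the effector locus whose mRNA passes the cis screen against the effector
and shows same-direction associations with at least 30% of the module's
targets (both thresholds configurable); modules without one are dropped.

Joint partitioning operates on the module-mean expected-state matrix
(rows: modules, entries: mean of p(+1) - p(-1) over targets). Both axes
are sorted by recursive two-way spectral bipartition: similarity is the
shifted Pearson correlation (1+r)/2, each node splits by the sign of the
second eigenvector of the normalized graph Laplacian, recursion stops
below 4 members. Two details matter in practice and are deliberate:

- *Child orientation.* After each split the two children are oriented so
  that their most similar members meet at the junction (the orientation of
  a spectral ordering is otherwise arbitrary). Without this, a split that
  cuts through a true block leaves the block's halves at opposite ends of
  the ordering.
- *Zero-variance rows* are placed last and flagged.

Boundaries on each sorted axis come from multiscale edge detection on two
1-D profiles: the mean over the opposite axis, and the leading-singular-
vector score profile (a data-weighted opposite-axis average). The second
profile is needed because rank-based quantization centres every module
profile, so module-axis block structure is invisible in plain means.
Each profile is smoothed with Gaussian kernels on a geometric scale ladder
adapted to the axis length (L/64, L/32, L/16, L/8, floored at 1); candidate
boundaries are zero crossings of the discrete second difference validated
by gradient magnitude at the crossing (at least 0.2 of the per-scale
maximum slope — Marr-Hildreth practice; this suppresses both noise
wiggles and the spurious midpoint crossings that arise between two distant
same-direction edges). A boundary is kept when it recurs within +-1 index
at 75% of the scales of some profile. Length-adaptive scales replace a
fixed ladder because fixed fine scales pass sampling noise on long axes
while fixed coarse scales over-smooth short ones.

## Pan-cancer aggregation

The membership matrix M counts modules containing gene i inside Super
Module j (columns tagged by cohort). Super Module Groups: average-linkage
hierarchical clustering on Jaccard similarity of the binarized columns,
cut top-down at the highest nodes whose two branches share a binary
enrichment signature (BH q <= 0.05) over six broad functional categories
(cell cycle, immune response, adhesion, ribosome, respiration, synapse);
the gene-overlap variant of the stopping rule is available behind the same
interface. Gene Groups: gene i belongs to group k when its summed
membership count clears a binomial upper tail under uniform random
assignment of the group's module memberships (each membership lands on a
given gene with probability 1/n_genes), BH-adjusted; genes bucket by
identical bit vectors, buckets of at least 20 genes (configurable) become
Gene Groups. Meta Gene Groups assign each Gene Group to the seed category
(immune/inflammatory; development/neurogenesis/adhesion; cell cycle/DNA
repair) with the smallest enrichment q at q <= 0.05. Recurrent Effectors
over-occur among a group's Super Modules relative to random same-size
groups (permutation p, minimum count 3). The integrated view is the chained
product M1 · M2 · M3 of over-representation, effector-occurrence and
pathway-membership matrices, computed per occurrence sign.

## Artery Networks

For each (effector, target) pair, a random walker starts at the effector's
node, moves to out-neighbours with equal probability, and is absorbed at
the target or at sink nodes. Edge weights are conditional traversal
probabilities given that the walker reaches the target, computed exactly
from the absorbing-chain linear system (expected visits x one-step
probability x forward reach probability, normalized by the source's reach
probability); cycles are handled by the same solve, with a power-iteration
fallback capped at 8 steps for walks trapped in recurrent classes. Weights
accumulate over pairs (optional normalization by the number of
contributing pairs); the Artery Network keeps the top 5% of edges by
weight (or a fixed threshold), the consensus keeps edges present in a
majority of cohort arteries with mean weight, and node levels are 1 + the
shortest distance from the nearest effector anchor, capped at 4.

## Clinical and survival alignment

Categorical clinical features are retained when non-missing in at least a
quarter of the cohort with at least two values (numeric features with more
than 20 distinct values are treated as continuous and dropped). The
concentration coefficient is the fraction of samples carrying their
group's dominant value; its null distribution comes from label
permutations. Pan-cancer Sample Group codes binarize the three Meta Gene
Group means against their cross-group medians (code = 4 b1 + 2 b2 + b3).
Per-gene Cox log-hazard coefficients are univariate proportional-hazards
fits with Breslow tie handling (via scikit-survival), with an
observed-information standard error. p_diff = Pr(X1 > X2 + eps) - Pr(X1 <
X2 - eps) is evaluated exactly over all cross pairs (sorted-array
counting) up to 10^7 pairs, beyond which both samples are subsampled with
a fixed seed; eps defaults to 0.1 x the standard deviation of the
background sample. Note that the *signed* statistic is not monotone in eps
for asymmetric difference distributions — each one-sided probability is,
and that is the monotonicity the tests assert. K-group log-rank tests and
Kaplan-Meier curves come from lifelines.

## Cross-dataset validation

Sample partition trees reuse the spectral column trees; leaf centroids are
cluster-mean expression over shared genes. Two trees are aligned by
Needleman-Wunsch over their ordered leaf sequences (match cost 1 -
Pearson correlation of centroids, gap penalty 0.5), computed against both
orientations of the second tree because the global left-right orientation
of a spectral ordering is dataset-arbitrary; the non-crossing matching
respects both topologies, and the incompatibility score is total cost over
the longer sequence length, clipped to [0, 1]. Module expression coherence
is the p_diff between within-module and random-background correlation
distributions (labels "coherent" at >= 0.3, "moderately coherent" at >=
0.1). Association preservation re-screens (effector, target, direction)
triples in the external data: compatible when significant in the
discovery direction, incompatible when significant in the opposite one.
Tissue-specific genes require expression at least 2x a reference (row
median floored at a quarter of the row maximum) in exactly one tissue and
at most 0.5x elsewhere; these thresholds are heuristic and configurable.

## The synthetic-data generator

The generator emulates the statistical shape the pipeline assumes, not any
real genome:

- **Background genes** follow a gene-group x sample-group block design.
  Block means combine a nested on/off activation staircase with linear
  row/column trends and a row-by-column interaction
  (`synthetic.block_means`). The trend gives every group a distinct mean
  level (so block boundaries are visible to the profile-based detector);
  the staircase and interaction give every group a distinct centred
  pattern (so correlation-based spectral sorting can separate groups that
  share a level pattern — a pure staircase leaves the all-on and all-off
  groups with identical centred profiles, which no correlation method can
  split). Hidden states are emitted as state x scale + Gaussian noise
  (scale 1, sigma 0.5 by default).
- **Effectors** are sparse alterations (rate 0.25 by default). Continuous
  effector loci have a dominant alteration sign (85% of events), matching
  recurrently amplified OR deleted loci; somatic alteration rates are
  concentrated in an effector-specific "active" sample group (60% of
  events by default, cycled over groups), emulating subtype-enriched
  alterations — without this concentration the planted Sample Groups are
  statistically invisible to any clustering of module profiles (verified
  with a k-means ceiling experiment). SNP genotypes are germline
  (Binomial(2, 0.3)) and uniform across groups.
- **Planted targets** draw their hidden state from p(y|x) with the
  configured lambda and legal (type, direction) pairs cycled over
  effector types; trans-CNV and SNP effectors route through a dedicated
  regulator gene whose expression tracks the effector state.
- **The network** contains every planted effector -> (regulator ->)
  target path plus a configurable number of random decoy edges, with no
  self-loops.
- **Survival** is proportional-hazards on true gene-group activities
  (log-hazard = sum_g beta_g x mean group expression, exponential event
  times, baseline rate 1/1000 per day); censoring is uniform on (0, max
  event time) applied to a configurable fraction. **Clinical labels**
  equal the sample group's dominant value with probability rho (0.8 by
  default), else uniform over the other values, so the expected
  concentration coefficient is approximately rho.

What the generator does **not** emulate: genome coordinates, linkage
disequilibrium, batch effects, read-level noise, gene-length or GC biases,
dependence between omics layers beyond the planted paths, and non-
proportional hazards. Passing recovery tests therefore demonstrate the
correctness and calibration of the inference machinery under its own
modelling assumptions, not performance on real tumours.

## Problem sizes and determinism

Benchmarks run at desk scale, chosen to keep the full suite around a
minute while leaving clear recovery margins: effector recovery at n = 500
with 3 planted effectors and 5 decoys over 20 seeds; biclustering at 40
modules x 300 samples (4 x 3 blocks, noise 0.3) over 20 seeds; null
calibration with 1000-pair screens over 20 replicates; Cox recovery at
n = 1000. The end-to-end demo study uses two cohorts of 300 samples, 220
genes, 21 effectors and 60 planted targets. Every stochastic step takes a
seed; the pipeline derives per-stage seeds from the global seed by
hashing, and identical seeds reproduce byte-identical outputs. At this
scale a two-cohort study is too sparse for Gene Group calling (a gene
accumulates only a handful of module memberships, which cannot clear the
binomial null after multiplicity adjustment) — the pan-cancer operators
are therefore benchmarked on denser many-cohort membership matrices in
their own tests.

## Known limitations

- The chi-square references are asymptotic and, with soft quantization
  posteriors, conservative; permutation p-values carry the selection
  decisions.
- Fitted lambdas are attenuated relative to generating values by emission
  noise and rank quantization; effector-set recovery, directions and
  likelihood orderings are the supported inferences, not raw effect
  sizes.
- Boundary detection assumes blocks are expressed either in the axis-mean
  or the leading-singular-vector profile; block structure orthogonal to
  both (e.g. only in trailing components) is not detected.
- The tree alignment matches ordered leaf sequences; topology is
  respected through the non-crossing property rather than an explicit
  node-by-node recursion.
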