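# Methods

## The structural similarity matrix

Group-level structural covariance networks correlate regional grey-matter
volumes *across* subjects, so no single subject owns a network. This package
instead builds a per-subject network: for one subject, every pair of atlas
regions is compared by the Wasserstein-1 (Earth-Mover's) distance between
their empirical distributions of nonzero grey-matter voxel values,

    W1(u, v) = ∫ |F_u(x) − F_v(x)| dx,

where F_u, F_v are the empirical CDFs of the two regional voxel-value
multisets. The closed form attains the optimal-transport infimum in one
dimension, needs no histogram binning, and handles unequal region sizes
through the pooled-order-statistic evaluation. The resulting region × region
matrix is symmetric with a zero diagonal and is *distance-valued*: larger
entries mean less similar regions. No inversion or normalisation is applied.

Zeros and negative voxel values are background (negatives can arise from
interpolation of probability maps) and are excluded. Regions with no
positive voxels are dropout; an instance with strictly more than 10% dropped
regions is excluded outright, and missing entries are propagated as NaN,
never imputed. "Strictly" matters at the boundary: 11 of 116 regions
(9.48%) is kept, 12 of 116 (10.34%) is excluded.

Rejected alternatives, kept out deliberately: Kullback–Leibler divergence
(requires density estimation and is binning-sensitive) and leave-one-out
structural-covariance deltas (produce inconsistent saliency).

## Functional connectivity and the univariate channel

Functional matrices are plain Pearson correlations of region-averaged
timeseries; all-constant rows are dropout. The univariate channel is the
per-region mean of nonzero grey-matter voxels, repeated row-wise into a
square matrix solely to match the connectivity matrices' dimensionality
(entry (i, j) = vec_j, so each full-row convolution window sees the entire
regional profile; column orientation is available as a switch and recorded
in output provenance).

## Matched case-control balancing

Each ensemble member independently re-runs a stochastic greedy matching:
cases in seeded random order each take the nearest unused control that
matches exactly on sex and collection site and lies within calipers on age
(±3 y), mean framewise displacement (±0.1 mm) and intracranial volume
(±0.5 pooled s.d.). These caliper defaults operationalise "statistically
similar" and are config-exposed. The nearest-neighbour distance normalises
each covariate by its pooled s.d. (not by the calipers) so all three weigh
comparably; calipers only gate eligibility. Matching is at subject level —
all of a subject's scans travel together — and matched pairs are assigned
jointly to train/validation/test at an instance-count ratio of ~4:1:1 by a
lowest-fill-fraction rule, which keeps the realised ratio within one pair
of target. Balance is diagnosed by standardized mean differences (|SMD| <
0.2 is the conventional adequacy threshold).

## Scramble encoding and the network

A symmetric n × n matrix holds n(n−1)/2 unique off-diagonal entries; a
seeded uniform permutation lays them into an (n−1) × (n/2) rectangle
(115 × 58 = 6670 cells for a 116-region atlas). Scrambling deliberately
destroys spatial adjacency so saliency maps cannot inherit convolution-
geometry biases; the permutation is redrawn per ensemble member (a switch
restores a shared permutation). Odd region counts are unsupported — pad the
parcellation with one extra region if needed.

The classifier is one convolution layer of 256 filters spanning a full
rectangle row across all input channels (1 × n/2 × C), ReLU, then three
dense layers of 64 units with batch normalisation, ReLU and 0.5 dropout,
and a two-class softmax. Training is Adam on cross-entropy for 100 epochs
with a parameter snapshot per epoch; the snapshot with the highest
validation accuracy is kept (ties → earliest epoch). Batch size (64),
learning rate (1e-3) and initialisation are config fields recorded in the
run manifest. The network and its backward passes are implemented directly
on NumPy: training is bit-reproducible given the seed, and the intermediate
gradients that Grad-CAM and guided backpropagation need are directly
accessible. Each member z-scores every rectangle cell on its own training
set before the network; this concentrates the learned weights on
discriminative edges rather than on per-edge baseline magnitudes, which
materially sharpens downstream saliency. Channels may be any subset of
{structural, functional, univariate, covariate}.

## Ensemble aggregation and projection

Each member sees its own matched subset and split; only its own test-set
predictions are recorded, which structurally prevents train/test
contamination (an audit utility re-checks this from the run manifest). The
ensemble score of an instance is its mean probability over covering
members, and the final AUROC is P(score_case > score_control) + ½ P(tie)
over all case-control pairs.

AUROC grows with ensemble size towards a ceiling. The saturating curve
AUROC(m) = L − a·m^(−b), 0.5 ≤ L ≤ 1, a ≥ 0, b > 0, is fit by profiling b
on a log grid with constrained linear least squares for (L, a). The model
degenerates as b → 0 (a near-linear drift mimics saturation with an
arbitrarily inflated asymptote), so among all b whose error is within 5% of
the minimum the largest (most saturating) b is chosen — the smallest
asymptote the data cannot distinguish from the best fit — then polished by
bounded nonlinear least squares. The functional form is named in the
output; the fit is deterministic.

## Saliency and hub isolation

Per (model, instance): Grad-CAM at the single conv layer (channel weights =
row-averaged gradients of the target score; map = rectified weighted
activation sum, broadcast across each rectangle row) multiplied elementwise
by the guided-backpropagation input gradient, absolute value taken, decoded
through the member's permutation into region-pair space. The backpropagated
score is the case *log-odds* (case logit minus control logit) rather than
the raw case logit: the raw logit contains a common-mode gradient component
that the softmax cancels but |saliency| would not, and dropping it
measurably denoises the maps. The target class is "case" for every instance
(switchable to predicted class); maps are averaged over every data instance
in every member into the class activation map (CAM).

For hub isolation the CAM is treated as a dense weighted graph with edge
length 1/(value + ε), ε = 1e−12 × max value, so high-saliency edges carry
shortest paths; edge betweenness centrality (counts of source-target
shortest paths per edge, fractional on ties) concentrates weight on the
most-travelled comparisons; communities maximise weighted modularity
(seeded multi-restart greedy multi-level, best-of-Q, never below the
trivial partition's Q = 0). Within each community regions are ranked by the
sum of incident within-community CAM values; the global top-k hub list
ranks regions by total incident CAM strength. An alternative max-minus-
weight length rule is config-exposed.

CAMs are compared to per-edge case-control effect sizes: Cohen's d with
pooled s.d. (|d|, since saliency is sign-blind; signed d retained in
outputs), Mann-Whitney two-sided p, Benjamini–Hochberg q at 0.05 across
edges. Edges with zero pooled s.d. get missing d with a warning.

## The matched-vs-random pairing test

To ask whether structure and function share information, same-subject
structure/function matrix correlations are compared with mismatched-subject
correlations: n_pairs draws of each (with replacement), Welch's two-sample
two-sided t-test on the two correlation samples. Because draws resample a
finite instance pool, n_pairs far above the instance count inflates the
effective sample size and makes the test anticonservative; keep n_pairs
comparable to the number of instances for a calibrated null (the package's
null simulations use n_pairs equal to the instance count).

## The synthetic cohort

The generator emulates the three input kinds with known ground truth; every
generator is a pure function of (config, seed).

*Structural.* Region r's voxel law is loc_r + Gamma(shape_r, θ_r) with
location ~ U(0.05, 0.25), s.d. ~ U(0.05, 0.15) and shape ~ U(2, 5) drawn
once per cohort — right-skewed, strictly positive, with shape varying
across regions so distributional comparisons (not just means) carry signal.
Subjects add a per-region location jitter (s.d. 0.3 × region scale), the
between-subject variability that makes classification nontrivial. Cases in
planted regions receive a location shift of struct_effect × the
cohort-pooled between-subject s.d. (RMS of the jitter s.d.s) — one unit per
cohort, so every planted region carries the same standardized effect
regardless of its own nuisance scale. A mean-preserving "shape" mode
instead inflates the gamma's spread/skew at constant mean, so structural
similarity can beat univariate volumes by construction. Default sizes: 16
regions, 60–150 voxels per region, 200 cases / 200 controls.

*Functional.* A block latent-factor model: four contiguous region blocks,
loading 0.6 on the block factor plus unit noise, 120 timepoints; func_effect
adds a case-specific shared factor on designated edges (0 by default, so
the functional channel is a built-in negative control).

*Covariates.* Age ~ N(30, 8) y, mean FWD ~ N(0.15, 0.08) mm, ICV ~
N(1.5e6, 1.2e5) mm³, with case offsets (+3 y, +0.03 mm, +5e4 mm³ — each
roughly 0.4 pooled s.d.), 70% male, three sites. A feasibility guard
errors out when fewer than `match_yield_floor` (default 50%) of cases have
any eligible control under default calipers; exact sex+site matching at
1:1 case:control typically leaves 55–75% of cases matchable, which is the
realistic regime the matcher must operate in.

*Voxel emission.* For the NIfTI path, compact contiguous parcels on a
≤32³ grid hold each subject's sample values verbatim, so extraction
round-trips exactly.

What passing on this cohort does not show: robustness to registration
error, smoothing, scanner/site intensity effects, spatial autocorrelation,
or heterogeneous (non-binary, subtype-structured) case groups — none of
which the generator imitates.

## Null-safety checks

Three checks verify the pipeline invents no signal where none exists: a
label-shuffled classification run (ensemble AUROC near 0.5), the
matched-vs-random pairing test at nominal type-I rate, and near-zero
CAM-vs-effect correlation under independence. The label-shuffle check runs
on a 400-case / 400-control cohort with the shuffled AUROC averaged over
four independent shuffles: cross-validated evaluation under label
permutation carries a known pessimistic finite-sample bias (training-set
chance imbalances are anti-correlated in the held-out remainder), measured
here at ≈0.05 below chance for a 200/200 cohort and ≈0.01 for 400/400, and
a single run's sampling s.d. is ≈0.04 — both would otherwise confound the
quantity the check is after.

## Problem sizes used in tests

The verification suite runs at desk scale, chosen so the full pipeline is
exercised end to end: 16-region cohorts of 400 subjects, 10-member
ensembles, 10 independent end-to-end replicates, exhaustive graph oracles
up to 8 nodes, 200-run null calibrations. The reference analysis's scale
(116 regions, ~29k scans, 300 members) is supported by configuration but is
not an acceptance surface; the headline numbers of that analysis are not
reproducible at desk scale and are not asserted anywhere in the suite.

## Numerical choices

- Wasserstein: pooled-order-statistic integration; exact symmetry by
  construction; empty distributions raise.
- Pearson matrices are symmetrised against floating-point asymmetry and
  clipped to [−1, 1]; diagonals forced to 1.
- Batch-norm epsilon 1e−5; singleton training batches are skipped (batch
  statistics undefined); running statistics use momentum 0.9.
- Checkpoint ties break to the earliest epoch; dropout masks come from the
  member's seeded generator, so training is reproducible bit-for-bit.
- Modularity uses 20 seeded Louvain restarts; betweenness ε is relative
  (1e−12 × max) so the length transform is scale-free.
- Univariate CAM ranking breaks ties by ascending region id.

## Known limitations

- The CNN runs on CPU via NumPy; it is sized for desk-scale cohorts, not
  for the reference analysis's full scale on a single core.
- Guided backpropagation is known to produce partially input-agnostic
  maps on deep networks; with a single conv layer the composition behaves
  well here, but saliency fidelity on deeper variants is unverified.
- The projection fit's conservative tie-break slightly biases the
  recovered asymptote towards the observed maximum when the curve is far
  from saturation.
- The paper-scale ambiguity of whether controls were matched per instance
  or per subject is resolved per subject; the alternative would change set
  sizes for subjects with repeat scans.
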