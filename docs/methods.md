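# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data generators it tests against,
and the numerical and design choices made where more than one reasonable
option existed.

## The clustered grey wolf optimizer

The grey wolf optimizer (GWO) is a population metaheuristic in which the
three best solutions found so far — alpha, beta and delta — attract the
rest of the pack. At iteration t, wolf X is pulled toward each leader X_p
through

    K = |C ∘ X_p − X|,       candidate_p = X_p − A ∘ K,

with per-dimension stochastic coefficients A = 2·a·r1 − a and C = 2·r2
(r1, r2 ~ U[0,1]) and a control parameter a(t) = 2 − 2t/T that decays
linearly from 2 (exploration; |A| can exceed 1, pushing wolves away from
leaders) to 0 (exploitation; candidates collapse onto the leaders). The
new position is the arithmetic mean of the three leader candidates,
clamped to the search box.

The clustered variant (KCBGWO) partitions the pack by k-means on position
each iteration and assigns a *separate* alpha/beta/delta hierarchy inside
each cluster; every wolf follows its own cluster's leaders. The intent is
niching: sub-packs refine different basins instead of all collapsing onto
one global trio. The global best is tracked for reporting and for the
optional early-stop threshold only.

Binary mode represents positions as bit vectors. The three leader
candidates are computed from the bits as real numbers, averaged, and
squashed through the logistic transfer σ(x) = 1/(1+e^−x); each bit is then
set to 1 with that probability (strict `u < p` acceptance). Because σ of a
bounded average never reaches 0 or 1, binary dynamics remain stochastic
even at full convergence; reaching an exact binary optimum is
probabilistic, which the tests account for by fixing seeds.

Defaults follow the published protocol: population 30, 500 iterations,
K = 3 clusters, k-means capped at 100 Lloyd sweeps, reclustering every
iteration. The `leader_blend_weights` hook can weight the three leader
candidates unequally but defaults to the plain mean, because no defining
equation exists for the weighting factors tabulated alongside the
published hyperparameters.

### Randomness and reproducibility

Each run derives two independent streams from its seed: the position
stream (initialization plus, per iteration, one (N,3,D) uniform block for
r1, one for r2, and in binary mode one (N,D) acceptance block) and a
k-means stream used only for centroid seeding. Keeping clustering off the
position stream makes a K=1 run bit-identical to plain GWO with the same
seed — an equivalence the test suite asserts exactly. The multi-run
protocol seeds run i with `base_seed + i`.

### k-means details

Lloyd's algorithm with Euclidean distance; centroids seeded by sampling K
distinct wolves; stop at an assignment fixpoint or the iteration cap;
an emptied cluster is re-seeded from a random wolf. The within-cluster
sum of squares is non-increasing across sweeps and final centroids equal
their members' means (both tested, and the implementation is cross-checked
against scikit-learn's KMeans on well-separated data). Clusters with fewer
than four members fill the missing beta/delta roles with their best wolf;
fitness ties break by wolf index.

## Benchmark suite

The ten classical test functions (Sphere; Schwefel 2.22, 1.2, 2.21;
Generalized Rosenbrock; Schwefel 2.26; Rastrigin; Ackley; Griewank;
Generalized Penalized no. 1 with the u(x,10,100,4) penalty) use their
standard box domains and D = 30 by default. Schwefel 2.26 is implemented
as 418.9829·D − Σ x_i sin(√|x_i|) so its minimum is ≈ 0 and values are
positive. Evaluators validate dimension and finiteness only; box
feasibility is the optimizer's job (positions are clamped after each
blend). The trial protocol records the best fitness of each seeded run
and reports mean and population standard deviation across runs.

## Extreme learning machine

A single-hidden-layer feed-forward network with G hidden nodes: input
weights a (G×n) and biases c (G) are fixed (drawn uniformly in [−1,1], the
stated range, or supplied by the tuner); the hidden activation is the
logistic σ by default (linear and tanh available). Only the output
weights are learned, as the minimum-norm least-squares solution
w = M⁺T, where M[j,i] = f(a_i·x_j + c_i) and M⁺ is the Moore-Penrose
pseudoinverse (SVD with singular values below 1e-10 times the largest
treated as zero — rank-deficient hidden matrices from duplicate samples
are therefore harmless). With G equal to the number of distinct samples
the network interpolates its training set up to floating point, which is
the basis of the exact-interpolation acceptance check. Classification
uses one-hot targets with classes in sorted label order and row-wise
arg-max decisions; biases share the weights' [−1,1] draw range.

## KCBGWO-ELM tuning

The tuner optimizes the ELM's input weights and biases: a candidate is the
flattened G×n weight matrix followed by the G biases — dimension
G·(n+1), bounded to [−1,1], rejected above 10⁶ with advice to shrink G or
the feature space. Candidate fitness is the mean squared error between
the one-hot targets and the network outputs after the output weights are
re-solved by pseudoinverse for that candidate; by default the MSE is
measured on the training split itself (a literal reading of the stated
fitness), with an internal-holdout policy available. Because each history
entry is the best fitness so far, the returned model's training MSE never
exceeds the best initial candidate's — tested directly, along with a
Monte-Carlo check that tuning beats the median of 30 untuned random-weight
networks.

## Synthetic feature generator

Real inputs to the classifier would be fused CNN features of graded
fundus images; extracting those is out of scope, so the generator emulates
them as class-conditional isotropic Gaussians. The five class means sit on
mutually orthogonal coordinate directions scaled so that every pair of
means is exactly `separation` apart; features have standard deviation
`noise_scale` around their class mean. Defaults: the per-grade counts of
the IDRiD training distribution (134/20/84/74/49 for Normal through PDR),
20 dimensions, separation 3.0, unit noise — separation 3 at unit noise
gives realistically imperfect class overlap (mid-80s percent accuracy
for an untuned classifier), while the separability property tests use
separation 6 where the classes are Bayes-separable by construction.

What this generator does *not* emulate: the heavy-tailed, correlated,
non-negative activation statistics of real CNN features, within-class
multimodality, and label noise. Passing tests therefore demonstrate the
correctness of the optimization/classification machinery, not clinical
performance on retinal images.

Class balancing tops every minority class up to the majority count by
resampling existing class members and adding Gaussian jitter scaled by
`jitter_scale` times the per-feature class standard deviation (default
0.1). Added rows are provenance-flagged `synthetic`; originals are
preserved bit-exactly. This is a transparent feature-space stand-in for
generative augmentation of images, which is out of scope.

## Feature fusion bookkeeping

Named fusion strategies concatenate declared blocks in a fixed order:
FS1 = K1+K2+K3+K4 → 6016 columns, FS2 = L1+L2+L3 → 3328, FS3 =
M1+M2+M3 → 1280. Block identity, order, declared width and sample
alignment are enforced; no scaling is applied (an optional per-block
z-scoring switch exists, default off, since the source pipelines do not
document any).

## Evaluation metrics

Per class, one-vs-rest counts give Accuracy (TP+TN)/total, Sensitivity
TP/(TP+FN), Specificity TN/(TN+FP) and Precision TP/(TP+FP), each as a
percentage. A zero denominator yields an explicit `None` marker rather
than a coerced 0 or 100. Macro averages are unweighted class means
(undefined entries skipped); micro accuracy is the plain pooled fraction
correct. AUC is the rank-based (Mann-Whitney) form with ties counted
half, cross-checked against scikit-learn. The Jaccard index is
intersection over union with the both-empty case defined as 1 (perfect
agreement).

## Lesion screening

The screen is a fixed four-stage chain per polarity: binarize → refine
(morphological closing then opening with disc structuring elements, then
a size floor) → per-component geometric features → rule filter. Red
lesions are dark, bright lesions are light; RGB images are reduced by the
green channel (standard fundus practice; luminance available).

Binarization methods: Otsu (appropriate for genuinely bimodal
histograms), a fixed intensity quantile, and the default *robust* rule —
threshold at the image median minus (dark) or plus (bright) `k_sigma`
scaled median absolute deviations, k = 5. The robust rule is the default
because lesions cover at most a few percent of a fundus image: the
histogram stays effectively unimodal, so Otsu bisects the background, and
a fixed quantile marks a constant fraction of background noise that the
closing step then merges into compact false candidates. A 5-sMAD outlier
rule marks essentially no background while capturing lesions whose
contrast is large against the noise floor.

Geometric descriptors per 8-connected component: area (pixels), perimeter
(regionprops' weighted estimate, floored at the equivalent-disc
circumference 2√(πA) so the discrete estimate cannot undershoot a disc),
border complexity P²/(4πA) (1 for a disc), and elongation (major/minor
axis ratio of the second-moment ellipse; defined as 1 for a single pixel
and infinite for zero-thickness components). Default rules: area ≥ 8 px,
elongation ≤ 4, border complexity ≤ 3; a rejected component records the
first failed rule. Inside `screen` the refine stage keeps its size floor
at 1 so that small specks surface as `too-small` rejections rather than
disappearing silently; note that the default opening radius of 1 erases
1-pixel specks before they can be recorded — set `opening_radius=0` when
rejection-reason observability matters.

The synthetic fundus fixture renders hard-edged dark/bright discs
(contrast 0.2) on a 0.55-intensity background with a mild radial vignette
(amplitude 0.04) and Gaussian noise (σ = 0.02), returning exact truth
masks. Default layouts plant 3 red and 2 bright non-overlapping lesions
of radius 6–10 px on a 192×192 raster. On 20 seeded fixtures the default
screen recovers every planted lesion with no accepted call disjoint from
the 2-px-dilated truth, and the accepted-call union's Jaccard against
truth exceeds 0.6 (tested). Real fundus images add vessels, uneven
illumination and camera artefacts that this fixture does not model.

## Problem sizes used in the checks

The benchmark acceptance runs use the full published protocol (D = 30,
N = 30, T = 500, 30 runs — a few seconds per function here). Property
tests use smaller instances chosen for coverage per unit time: D ≤ 12
packs for the equivalence and monotonicity checks, 10–20-dimensional
feature spaces for the pipeline, 15×15 tuner populations for the
classifier properties, and 20 fixture seeds for the screening checks.

## Known limitations

- Clustered leadership helps niching but can slow exploitation on
  unimodal problems when clusters trap poor wolves with poor leaders;
  mean best values on multimodal tails (e.g. Ackley) are dominated by a
  few slow runs and vary by an order of magnitude across seed batches.
- Binary mode cannot represent deterministic convergence (sigmoid
  probabilities are interior), so exact binary optima are found with high
  probability, not certainty.
- The ELM tuner re-solves a pseudoinverse per candidate evaluation;
  costs grow as O(H·G² ) per evaluation and the candidate space as
  G·(n+1), so wide feature vectors call for the dimension guard.
- Metrics with empty denominators propagate `None`; downstream consumers
  must handle the marker explicitly.
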