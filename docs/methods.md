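# Methods

## The model and the selection problem

Observations x_1, …, x_n ∈ R^p come from a K-class Gaussian model:
conditional on its true class y*_i ∈ {1..K}, X_i ~ N_p(μ_{y*_i}, Σ_w)
with a common within-class covariance Σ_w. Labels are only partially
observed: y_i = y*_i with probability γ and y_i = 0 (unlabeled)
otherwise, so γ = 1 is classification and γ = 0 is clustering. The
quantity that measures how much a coordinate helps distinguish the
classes is the corresponding diagonal entry of the whitened
between-class covariance Σ_w^{-1} Σ_b, where
Σ_b = Σ_k π_k (μ_k − μ̄)(μ_k − μ̄)ᵀ has rank ≤ K − 1. In the two-class
case the j-th entry is the squared Mahalanobis separation contributed by
coordinate j, and the one-dimensional Bayes risk along j is a decreasing
function of it. The signal set S0 is where these entries are nonzero; in
expression studies S0 is the handful of genes that separate the
phenotypes, buried among thousands of irrelevant ones.

When p ≫ n, Σ_w cannot be inverted, but if |S0| is small the problem
survives projection: for any axis-aligned projection P (a selection of d
coordinates), the projected data have whitened between-class covariance
(PΣ_wPᵀ)^{-1}(PΣ_bPᵀ), estimable as soon as d ≤ n − K.

## The ensemble selector

`sharp_ssl_select` draws A·B axis-aligned projections uniformly at
random, applies a base learner to each projected dataset to get
nonnegative per-coordinate importance scores, keeps within each of the A
groups the projection with the largest score sum (ties to the smallest
index), back-projects the winners' scores to R^p, averages them, and
returns the top-l coordinates. Grouping rather than global selection
keeps the A chosen projections i.i.d. conditional on the data, which is
what makes the aggregated scores concentrate as A grows. Projections may
repeat (no deduplication), and each (a, b) cell runs on an independent
random stream spawned from the root seed, so results do not depend on
evaluation order.

Two base learners estimate the projected whitened between-class
diagonal:

* **Labeled moments** (`labeled_importance`): class counts, means and
  pooled covariances from the labeled rows only; the within-class
  covariance is projected onto a constraint family (diagonal-PSD by
  default, full-PSD optional) and pseudoinverted if singular (singular
  values below 1e-12 of the largest are dropped). Scores are clipped at
  0. With fewer than two labeled classes the between-class covariance is
  0 and so are the scores.
* **Semi-supervised EM** (`em_importance`): fits the Gaussian mixture by
  EM where labeled rows keep exact one-hot responsibilities and
  unlabeled rows get posterior softmax weights (equal priors). The M
  step has closed forms for three constraint families: unconstrained,
  diagonal covariance, and the two-component symmetric family
  (means ±μ, identity covariance), whose update is the classical
  μ ← (1/n){Σ_labeled (−1)^y z + Σ_unlabeled z tanh⟨z, μ⟩}. After the
  final iteration the soft between-class covariance
  Γ_b = Σ_k p̃_k (μ̂_k − μ̂_tot)(μ̂_k − μ̂_tot)ᵀ (p̃ the mean
  responsibilities) is whitened by the final M-step covariance and its
  0-clipped diagonal returned. With M > 1 restarts, the run whose
  whitened matrix has the smallest median operator-norm distance to the
  others is kept (ties to the first).

## Tunable parameters

| parameter | default | meaning / why |
|---|---|---|
| A | 150 | projection groups; recovery probability improves with A |
| B | 75 | projections per group; sharpens within-group selection |
| d | user | projected dimension; ideally ≥ |S0|, must be ≤ n − K |
| l (`n_select`) | user | variables returned; no automatic rule exists |
| M | 1 | EM restarts; 1 with the deterministic hierarchical init |
| T | 100 | EM iteration cap |
| init_policy | hierarchical | Ward-linkage hard clustering, moment estimates; `random` gives the symmetric-family sphere init (radius 0.3) |
| loglik_rtol | 1e-5 | relative log-likelihood stopping (see below) |

A = 150, B = 75 are the settings of the simulation studies; they are a
compute/accuracy trade-off, not fitted constants.

### Convergence policy

`run_em` stops after T iterations, when the largest parameter change
drops below 1e-8, or — when `loglik_rtol` is set — when the relative
change in observed-data log-likelihood falls below it. The ensemble
scorer uses the log-likelihood rule (rtol 1e-5, the mclust convention)
by default: on projections that carry no signal the parameter-change
criterion essentially never triggers within the cap because EM drifts
interminably along flat spurious directions, while the likelihood
plateaus almost immediately. The choice affects runtime, not selections:
both stopping rules give the same aggregated scores to ~1e-3 and
identical selected sets in tests.

### Initialisation

The hierarchical policy cuts a Ward-linkage dendrogram of the (projected)
data at K clusters and takes moment estimates of the hard partition as
initial parameters; it is deterministic, so M = 1 suffices. Cluster
numbering follows first appearance; `hierarchical_init(..., y=...)`
instead numbers clusters by maximum agreement with the observed labels
(an assignment problem on the label/cluster contingency table). The
label-matched variant matters for the symmetric two-component family:
with an arbitrarily signed init, EM has a stable wrong-sign fixed point
displaced by about 2γ‖μ*‖ whenever 0 < γ < 1/2 — the labeled rows pull
one way and the unlabeled tanh term the other — and the restart
selector cannot detect it because the whitened between-class matrix is
sign-invariant. Matching the initial cluster identities to the observed
labels removes that basin.

## Implementation of the ensemble inner loop

Scoring an ensemble means ~A·B ≈ 11,000 independent small EM fits. The
default configuration (EM base, hierarchical init, M = 1, unconstrained
family) runs through a numba-compiled kernel (`_ensemble.py`) that
gathers each projection, builds the Ward partition (a nearest-neighbour
chain implementation operating on squared distances with the
Lance–Williams update; it produces the same partitions as scipy's ward
linkage), and iterates EM with exactly the reference stopping rules. The
kernel reproduces the pure numpy/scipy path to ~1e-14 per projection;
this equivalence is asserted in the test suite, and any other
configuration takes the generic per-projection path.

## Downstream assignment and metrics

After selection, `final_fit` runs either the semi-supervised EM
(unconstrained family, hierarchical init; rows get their
maximum-posterior class) or plug-in Gaussian LDA estimated from the
labeled rows on the selected coordinates. The same data are used for
selection and final fit, as in the simulation protocol; no sample
splitting. Misclustering is the fraction of disagreements minimised over
relabelings of the estimate, computed by optimal assignment on the K×K
confusion matrix (equal to full permutation enumeration; asserted for
K ≤ 5). Mean-estimation quality uses the swap-minimised Frobenius loss
for two-class mean pairs and the sign-flip loss
min(‖μ̂−μ*‖, ‖μ̂+μ*‖) for the symmetric model.

## The simulation designs

`synthetic` draws equal-probability K-component Gaussian mixtures with
sparse mean templates: a K = 3 "three-cluster" template with overlapping
two-coordinate supports and equal pairwise mean distances, and a K = 2
"symmetric-pair" template μ_1 = −μ_2 supported on the first s0
coordinates. SNR is the smallest pairwise mean distance divided by
√(tr(Σ_w)/p); templates are rescaled with the realised trace of the
drawn covariance so the generated SNR matches the design exactly (for
the anisotropic covariance — Haar-rotated Unif[0,2] spectrum — the
realised rather than expected trace is used; Euclidean distances on the
raw scale). Labels are hidden i.i.d. with probability 1 − γ, or by a
first-n_L prefix for the symmetric low-dimensional model. The default
labeled fraction is γ = 0.2: a realistic minority-labeled regime within
the γ ∈ (0, 1/2] range the semi-supervised analyses consider. Bayes
risks come from a Monte-Carlo evaluation of the exact maximum-posterior
rule (200,000 draws by default, SE < 0.002) with closed forms for the
two-class and one-dimensional cases as cross-checks.

What the generator does not emulate: heavy tails, per-class covariance
heterogeneity, dependent label-hiding, or batch structure. Passing tests
demonstrate correct behaviour under the Gaussian, common-covariance,
missing-completely-at-random model only.

## Problem sizes used in the checked experiments

The statistical test suite runs the full pipeline at n = 250, p = 50,
K = 3, s0 = 3, γ = 0.2 with A = 150, B = 75, d = l = 3 (20 repetitions
per SNR; 10 for the ensemble-size sweep), and the symmetric-model EM
experiment at n = 2000, d = 3, ‖μ*‖ = 1.5 with 100 repetitions. The
acceptance script reruns the same designs at 8 repetitions. These sizes
keep full runs to minutes on a single CPU while leaving the Monte-Carlo
error well inside the asserted margins.

## Known limitations

* **Unsupervised selection at moderate n.** With γ = 0 the unconstrained
  EM base overfits pure-noise projections: a K = 3 common-covariance fit
  to isotropic noise (n = 250, d = 3) has a spurious whitened
  between-class trace of ≈ 1.3 — the same value R's mclust produces —
  which is comparable to the genuine score of a projection carrying one
  signal coordinate at SNR 3. Group selection then cannot reliably
  prefer signal-bearing projections, and support recovery degrades
  badly. A modest labeled fraction (γ ≈ 0.1–0.2) anchors the labeled
  rows' responsibilities, collapses the spurious fits and restores
  near-certain recovery; the symmetric-family base (variance fixed at
  identity) is also immune by construction. Fully unsupervised use
  should prefer larger sample sizes or a constrained family, and its
  results should be read with this caveat.
* The constraint-set machinery covers the three families used here, not
  arbitrary convex constraint sets.
* Priors are fixed uniform in the E step; strongly unbalanced classes
  are not modelled.
* l must be chosen by the user; no data-driven rule is provided.
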