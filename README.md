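# sharpssl

High-dimensional semi-supervised learning by **s**elective
**h**igh-dimensional **a**xis-aligned **r**andom **p**rojections:
identify the few variables that separate the classes, then hand the
low-dimensional problem to a standard method.

## Who this is for

Analysts with an n × p data matrix (p possibly in the thousands — e.g.
gene-expression profiles), class labels for only a fraction γ of the
rows (γ = 0 is clustering, γ = 1 classification), and reason to believe
that a small set S0 of variables carries the class signal.

## The method

Under the K-class Gaussian model X | Y = k ~ N_p(μ_k, Σ_w), the
usefulness of a subspace V for telling classes apart is the generalised
Rayleigh quotient

    J(V) = tr{ (VᵀΣ_w V)^{-1} (VᵀΣ_b V) },    Σ_b = Σ_k π_k (μ_k − μ̄)(μ_k − μ̄)ᵀ,

and coordinate j's individual worth is the j-th diagonal entry of the
whitened between-class covariance Σ_w^{-1}Σ_b — zero off the signal set
S0. Σ_w is not invertible when p > n, but every d-coordinate projection
(d ≤ n − K) of the problem is well posed. The selector therefore:

1. draws A groups of B axis-aligned random projections into d dimensions;
2. scores each projected dataset with a base learner ψ that estimates
   the projected whitened between-class diagonal — either labeled-data
   moments (LDA-style) or a semi-supervised Gaussian EM whose E step
   pins observed labels and soft-labels the rest;
3. keeps the highest-scoring projection per group (largest score sum),
   back-projects the winners' scores into R^p and averages them;
4. returns the l variables with the largest aggregated scores.

A final class assignment is obtained by running the EM learner (or
plug-in LDA) on the selected coordinates alone. A matching simulation
module generates sparse-mean Gaussian-mixture designs at prescribed
signal-to-noise ratio SNR = min_{k≠k'} ‖μ_k − μ_k'‖ / √(tr(Σ_w)/p),
with Monte-Carlo and closed-form Bayes-risk oracles for calibration.

See `docs/methods.md` for estimators, constraint families,
initialisation and convergence rules, and known limitations.

## Worked example

Simulate a 250 × 50 three-class problem whose signal lives on three
coordinates, with 20% of labels observed, then select and classify:

```
sharpssl simulate --n 250 --p 50 --K 3 --s0 3 --snr 3 --gamma 0.2 \
    --seed 7 --out demo
sharpssl fit demo/matrix.csv demo/labels.txt \
    --d 3 --l 3 --A 150 --B 75 --seed 7 --out demo-run
sharpssl evaluate demo-run/predictions.csv demo/labels_true.txt
```

which prints

```
wrote dataset (250 x 50) to demo
{
  "n": 250,
  "p": 50,
  "K": 3,
  "selected": [
    1,
    2,
    3
  ]
}
misclustering rate: 0.1200
```

The simulator plants the signal on (1-based) columns 1–3 and records
them in `demo/design.json`; `selected: [1, 2, 3]` means the ensemble
recovered exactly the planted support, and the final EM fit on those
three columns misclassifies 12% of observations — close to the Bayes
risk of this design (≈ 0.114 at SNR 3 by Monte Carlo). `demo-run/` also
contains the full aggregated score vector (`scores.csv`), per-group
diagnostics and a manifest sufficient to reproduce the run.

The same interface is available programmatically:

```python
from sharpssl import SharpSSLConfig, SimulationDesign, sample_mixture, sharp_ssl_select

sample = sample_mixture(SimulationDesign(n=250, p=50, K=3, s0=3, snr=3, gamma=0.2, seed=7))
config = SharpSSLConfig(d=3, n_select=3, A=150, B=75, seed=7)
result = sharp_ssl_select(sample.X, sample.y, 3, config)
result.selected  # 0-based indices of the selected variables
```

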