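"""Final class assignment on the selected variables, and evaluation metrics.

Once the ensemble has picked a small variable set, any low-dimensional
semi-supervised method can finish the job.  Two are provided: the
semi-supervised EM learner (assign each point to its maximum-posterior
class) and plug-in Gaussian LDA fitted on the labeled rows.  Evaluation
uses the permutation-minimised misclustering rate, plus the mean-matrix
Frobenius loss and the sign-flip mean loss used for the two-component
symmetric model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import base_em, base_labeled
from .base_em import MixtureParams
from .base_labeled import ClassMoments


@dataclass(frozen=True)
class LabelAssignment:
    """Predicted labels in {1..K} and the fitted low-dimensional model."""

    labels: np.ndarray
    model: MixtureParams | ClassMoments


def final_fit(
    Z: np.ndarray,
    y: np.ndarray,
    K: int,
    method: str = "em",
    T: int = 100,
) -> LabelAssignment:
    """Fit a low-dimensional model on the selected coordinates and label all rows.

    ``method="em"``: semi-supervised EM (unconstrained family,
    hierarchical initialisation); each row gets its maximum-soft-label
    class, with observed labels kept as-is.  ``method="lda"``: plug-in
    Gaussian LDA estimated from the labeled rows (class proportions,
    means and pooled within-class covariance, pseudoinverse if
    degenerate), applied to every row.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y).astype(int)
    if method == "em":
        init = base_em.hierarchical_init(Z, K)
        params, L = base_em.run_em(
            Z, y, init, "unconstrained", T, loglik_rtol=base_em.LOGLIK_RTOL
        )
        return LabelAssignment(labels=np.argmax(L, axis=1) + 1, model=params)
    if method == "lda":
        if not (y > 0).any():
            raise ValueError("LDA requires at least one labeled observation")
        mom = base_labeled.class_moments(Z, y, K)
        if np.allclose(mom.within, 0.0):
            # e.g. one labeled point per class: fall back to the identity
            # metric, i.e. the nearest-class-mean rule
            gw_pinv = np.eye(Z.shape[1])
        else:
            gw_pinv = np.linalg.pinv(
                mom.within, rcond=base_labeled.RCOND, hermitian=True
            )
        # discriminant: x' W mu_k - 0.5 mu_k' W mu_k + log pi_k; classes
        # absent from the labeled set get log-prior -inf (never predicted)
        log_priors = np.full(K, -np.inf)
        present = mom.counts > 0
        log_priors[present] = np.log(mom.counts[present] / mom.n_labeled)
        scores = (
            Z @ gw_pinv @ mom.means.T
            - 0.5 * np.einsum("kd,de,ke->k", mom.means, gw_pinv, mom.means)
            + log_priors
        )
        return LabelAssignment(labels=np.argmax(scores, axis=1) + 1, model=mom)
    raise ValueError(f"unknown method {method!r}")


def misclustering_rate(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Fraction of disagreements, minimised over relabelings of the estimate.

    Computed via optimal assignment on the K x K confusion matrix, which
    equals full enumeration over the permutation group.
    """
    y_true = np.asarray(y_true).astype(int)
    y_hat = np.asarray(y_hat).astype(int)
    if y_true.shape != y_hat.shape:
        raise ValueError("label vectors have different lengths")
    if y_true.min() < 1 or y_hat.min() < 1:
        raise ValueError("labels must lie in {1, ..., K}")
    K = int(max(y_true.max(), y_hat.max()))
    n = y_true.shape[0]
    confusion = np.zeros((K, K))
    np.add.at(confusion, (y_hat - 1, y_true - 1), 1.0)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return 1.0 - float(confusion[rows, cols].sum()) / n


def misclustering_rate_bruteforce(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Reference implementation by enumeration over all K! relabelings."""
    y_true = np.asarray(y_true).astype(int)
    y_hat = np.asarray(y_hat).astype(int)
    K = int(max(y_true.max(), y_hat.max()))
    best = np.inf
    for perm in permutations(range(1, K + 1)):
        mapped = np.asarray(perm)[y_hat - 1]
        best = min(best, float(np.mean(mapped != y_true)))
    return best


def mean_frobenius_loss(
    est: tuple[np.ndarray, np.ndarray], true: tuple[np.ndarray, np.ndarray]
) -> float:
    """Frobenius distance between two-class mean pairs, up to swapping."""
    m1, m2 = (np.asarray(v, dtype=float) for v in est)
    t1, t2 = (np.asarray(v, dtype=float) for v in true)
    if m1.shape != t1.shape or m2.shape != t2.shape or m1.shape != m2.shape:
        raise ValueError("mean shapes disagree")
    direct = np.sqrt(np.sum((m1 - t1) ** 2) + np.sum((m2 - t2) ** 2))
    swapped = np.sqrt(np.sum((m2 - t1) ** 2) + np.sum((m1 - t2) ** 2))
    return float(min(direct, swapped))


def sign_flip_loss(mu_hat: np.ndarray, mu_star: np.ndarray) -> float:
    """min(||mu_hat - mu_star||, ||mu_hat + mu_star||)."""
    mu_hat = np.asarray(mu_hat, dtype=float).ravel()
    mu_star = np.asarray(mu_star, dtype=float).ravel()
    if mu_hat.shape != mu_star.shape:
        raise ValueError("vectors have different dimensions")
    return float(
        min(np.linalg.norm(mu_hat - mu_star), np.linalg.norm(mu_hat + mu_star))
    )
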