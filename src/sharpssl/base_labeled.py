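"""Labeled-data base learner.

Estimates per-coordinate importance scores from the labeled observations
only: the score vector is the diagonal of ``(Proj_C Gw)^+ Gb`` where ``Gw``
and ``Gb`` are the within- and between-class sample covariance matrices of
the labeled rows, and ``Proj_C`` is the Euclidean projection onto a
constraint set of symmetric PSD matrices.  The diagonal of the whitened
between-class covariance measures, coordinate by coordinate, how well that
coordinate separates the classes: in the two-class Gaussian case the j-th
entry is the squared Mahalanobis separation contributed by coordinate j,
and the one-dimensional Bayes risk along coordinate j is decreasing in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError

#: singular values below RCOND * largest are treated as zero in pseudoinverses
RCOND = 1e-12

CONSTRAINT_FAMILIES = ("diagonal", "psd")


@dataclass(frozen=True)
class ClassMoments:
    """First and second moments of labeled data, by class.

    ``counts[k]`` is the number of labeled observations in class ``k + 1``;
    classes absent from the labeled set have count 0 and mean 0.
    ``within`` and ``between`` are the pooled within-class and the
    count-weighted between-class covariance matrices of the labeled rows
    (``between`` has rank at most K-1).
    """

    counts: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    grand_mean: np.ndarray  # (d,)
    within: np.ndarray  # (d, d)
    between: np.ndarray  # (d, d)

    @property
    def n_labeled(self) -> int:
        return int(self.counts.sum())


def class_moments(Z: np.ndarray, y: np.ndarray, K: int) -> ClassMoments:
    """Compute per-class counts/means and within/between covariances.

    Labels take values in {0, 1, ..., K} with 0 meaning "unlabeled";
    unlabeled rows are excluded from every sum.  All normalisers use the
    labeled count n'.

    Raises
    ------
    DegenerateDataError
        If no row is labeled.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y)
    n, d = Z.shape
    if y.shape[0] != n:
        raise ValueError("Z and y have different lengths")
    if K < 2:
        raise ValueError("need K >= 2 classes")
    if y.min() < 0 or y.max() > K:
        raise ValueError("labels must lie in {0, ..., K}")

    labeled = y > 0
    n_prime = int(labeled.sum())
    if n_prime == 0:
        raise DegenerateDataError("no labeled observations")

    counts = np.bincount(y[labeled].astype(int), minlength=K + 1)[1:].astype(float)
    means = np.zeros((K, d))
    for k in range(K):
        if counts[k] > 0:
            means[k] = Z[y == k + 1].mean(axis=0)
    grand = Z[labeled].mean(axis=0)

    dev = Z[labeled] - means[y[labeled].astype(int) - 1]
    within = dev.T @ dev / n_prime
    mdev = means - grand
    # absent classes (count 0) carry weight 0 regardless of their zero mean
    between = (mdev.T * (counts / n_prime)) @ mdev
    return ClassMoments(counts, means, grand, within, 0.5 * (between + between.T))


def project_to_constraint(G: np.ndarray, family: str = "diagonal") -> np.ndarray:
    """Euclidean (Frobenius) projection of a symmetric matrix onto a family.

    ``"diagonal"``: diagonal PSD matrices — zero the off-diagonal entries
    and clip negative diagonal entries at 0.  ``"psd"``: all PSD matrices —
    eigendecompose and clip negative eigenvalues at 0.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(G, G.T, atol=1e-8 * max(1.0, np.abs(G).max())):
        raise ValueError("expected a symmetric matrix")
    if family == "diagonal":
        return np.diag(np.clip(np.diag(G), 0.0, None))
    if family == "psd":
        vals, vecs = np.linalg.eigh(0.5 * (G + G.T))
        return (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    raise ValueError(f"unknown constraint family {family!r}")


def labeled_importance(
    Z: np.ndarray, y: np.ndarray, K: int, family: str = "diagonal"
) -> np.ndarray:
    """Importance scores from labeled rows: diag((Proj_C Gw)^+ Gb).

    The pseudoinverse handles a singular (after projection) within-class
    covariance; scores are clipped at zero so the output lies in the
    nonnegative orthant required of a base procedure.  If fewer than two
    classes appear among the labeled rows the between-class covariance is
    zero and so are the scores.
    """
    mom = class_moments(Z, y, K)
    gw = project_to_constraint(mom.within, family)
    if family == "diagonal":
        diag = np.diag(gw)
        inv = np.zeros_like(diag)
        nz = diag > RCOND * max(diag.max(initial=0.0), 1e-300)
        inv[nz] = 1.0 / diag[nz]
        scores = inv * np.diag(mom.between)
    else:
        gw_pinv = np.linalg.pinv(gw, rcond=RCOND, hermitian=True)
        scores = np.diag(gw_pinv @ mom.between)
    return np.clip(scores, 0.0, None)
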