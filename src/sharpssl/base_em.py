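"""Semi-supervised Gaussian EM base learner.

Fits a K-component Gaussian mixture with common within-class covariance to
partially labeled low-dimensional data.  The E step computes soft labels:
rows with an observed label are exact one-hot indicators, unlabeled rows
get the softmax of negative half squared Mahalanobis distances to the
current class means (equal prior weights).  The M step minimises the
soft-label-weighted Gaussian objective over a constraint family:

- ``"unconstrained"``: free means, free common covariance;
- ``"diagonal"``: free means, diagonal common covariance;
- ``"symmetric"``: two components with means (-mu, +mu) and identity
  covariance, whose closed-form update is the classical tanh iterate
  ``mu <- (1/n) { sum_labeled (-1)^y z + sum_unlabeled z tanh<z, mu> }``.

After the final iteration the learner forms a soft between-class
covariance from the final responsibilities and returns the diagonal of
the whitened between-class covariance ``Gw^{-1} Gb`` as importance
scores.  With several random restarts, the run whose whitened matrix has
the smallest median operator-norm distance to the other runs is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import cho_factor, cho_solve

from .errors import DegenerateDataError

EM_FAMILIES = ("unconstrained", "diagonal", "symmetric")

#: default early-stopping tolerance on the maximum parameter change
PARAM_TOL = 1e-8
#: default relative change in observed-data log-likelihood below which the
#: EM iteration is considered converged (the convention of mclust-style
#: implementations); used by the ensemble importance scorer
LOGLIK_RTOL = 1e-5


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of a K-component common-covariance Gaussian mixture."""

    means: np.ndarray  # (K, d)
    within: np.ndarray  # (d, d)
    weights: np.ndarray | None = None  # (K,), defaults to uniform

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        object.__setattr__(self, "means", means)
        object.__setattr__(
            self, "within", np.atleast_2d(np.asarray(self.within, dtype=float))
        )
        if self.K < 2:
            raise ValueError("need K >= 2 components")
        if self.within.shape != (self.d, self.d):
            raise ValueError("within-class covariance has wrong shape")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.K,) or w.min() < 0:
                raise ValueError("weights must be a nonnegative length-K vector")
            object.__setattr__(self, "weights", w / w.sum())

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def priors(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.K, 1.0 / self.K)
        return self.weights


def _mahalanobis_sq(Z: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(n, K) matrix of squared Mahalanobis distances to each class mean."""
    try:
        factor = cho_factor(params.within, lower=True)
    except np.linalg.LinAlgError as err:
        raise DegenerateDataError("within-class covariance is singular") from err
    # guard against cho_factor succeeding on a semi-definite matrix
    if np.abs(np.diag(factor[0])).min() < 1e-154:
        raise DegenerateDataError("within-class covariance is singular")
    out = np.empty((Z.shape[0], params.K))
    for k in range(params.K):
        diff = (Z - params.means[k]).T  # (d, n)
        out[:, k] = np.einsum("dn,dn->n", diff, cho_solve(factor, diff))
    return out


def e_step(Z: np.ndarray, y: np.ndarray, params: MixtureParams) -> np.ndarray:
    """Soft labels: one-hot for labeled rows, posterior softmax otherwise."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y).astype(int)
    n = Z.shape[0]
    K = params.K
    if Z.shape[1] != params.d:
        raise ValueError("Z and params disagree on dimension")
    if y.min() < 0 or y.max() > K:
        raise ValueError("labels must lie in {0, ..., K}")
    q = -0.5 * _mahalanobis_sq(Z, params)
    q -= q.max(axis=1, keepdims=True)
    L = np.exp(q)
    L /= L.sum(axis=1, keepdims=True)
    labeled = y > 0
    if labeled.any():
        L[labeled] = 0.0
        L[labeled, y[labeled] - 1] = 1.0
    return L


def m_step(Z: np.ndarray, L: np.ndarray, family: str = "unconstrained") -> MixtureParams:
    """Closed-form minimiser of the soft-label Gaussian objective."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    n, d = Z.shape
    K = L.shape[1]
    if L.shape[0] != n:
        raise ValueError("Z and L have different lengths")
    if not np.allclose(L.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of the soft-label matrix must sum to 1")
    if family not in EM_FAMILIES:
        raise ValueError(f"unknown constraint family {family!r}")

    if family == "symmetric":
        if K != 2:
            raise ValueError("symmetric family requires K = 2")
        mu = (L[:, 1] - L[:, 0]) @ Z / n
        return MixtureParams(np.stack([-mu, mu]), np.eye(d))

    s = L.sum(axis=0)  # (K,)
    if np.any(s == 0):
        warnings.warn("a class has zero soft mass; its mean is set to 0")
    mu = np.zeros((K, d))
    nz = s > 0
    mu[nz] = (L.T @ Z)[nz] / s[nz, None]
    within = (Z.T @ Z - (mu.T * s) @ mu) / n
    within = 0.5 * (within + within.T)
    if family == "diagonal":
        within = np.diag(np.diag(within))
    return MixtureParams(mu, within)


def observed_nll(Z: np.ndarray, y: np.ndarray, params: MixtureParams) -> float:
    """Observed-data negative log-likelihood (equal prior weights).

    Labeled rows contribute their class-conditional density, unlabeled
    rows the mixture density.  EM alternation never increases this.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y).astype(int)
    n, d = Z.shape
    K = params.K
    q = -0.5 * _mahalanobis_sq(Z, params)
    _, logdet = np.linalg.slogdet(params.within)
    const = -0.5 * logdet - 0.5 * d * np.log(2 * np.pi) - np.log(K)
    labeled = y > 0
    ll = 0.0
    if labeled.any():
        ll += (q[labeled, y[labeled] - 1] + const).sum()
    if (~labeled).any():
        qu = q[~labeled]
        mx = qu.max(axis=1)
        ll += (mx + np.log(np.exp(qu - mx[:, None]).sum(axis=1)) + const).sum()
    return -float(ll)


def run_em(
    Z: np.ndarray,
    y: np.ndarray,
    init: MixtureParams,
    family: str = "unconstrained",
    T: int = 100,
    param_tol: float = PARAM_TOL,
    loglik_rtol: float | None = None,
) -> tuple[MixtureParams, np.ndarray]:
    """Alternate E and M steps from ``init`` for up to ``T`` iterations.

    Stops early when the largest parameter change falls below
    ``param_tol``, or (if ``loglik_rtol`` is given) when the relative
    change in observed-data log-likelihood falls below it.  Returns the
    final parameters together with soft labels recomputed from them.
    """
    if T < 1:
        raise ValueError("need T >= 1 iterations")
    params = init
    prev_ll = np.inf
    for _ in range(T):
        L = e_step(Z, y, params)
        new = m_step(Z, L, family)
        delta = max(
            np.abs(new.means - params.means).max(),
            np.abs(new.within - params.within).max(),
        )
        params = new
        if delta < param_tol:
            break
        if loglik_rtol is not None:
            ll = -observed_nll(Z, y, params)
            if np.abs(ll - prev_ll) < loglik_rtol * (1.0 + np.abs(ll)):
                break
            prev_ll = ll
    return params, e_step(Z, y, params)


def soft_between_covariance(
    L: np.ndarray, params: MixtureParams
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-label between-class covariance.

    With soft class proportions ``p_k = mean_i L_{i,k}`` this is the
    ``p``-weighted covariance of the class means about their weighted
    mean; it is PSD with rank at most K-1 and invariant to a global sign
    flip of the means (with matching responsibilities).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != params.K:
        raise ValueError("L and params disagree on the number of classes")
    pk = L.mean(axis=0)
    mu_tot = pk @ params.means
    dev = params.means - mu_tot
    between = (dev.T * pk) @ dev
    return mu_tot, 0.5 * (between + between.T)


def select_run(Qs: list[np.ndarray]) -> int:
    """Pick the run in best agreement with the others.

    Returns the 0-based index minimising the median operator-norm
    distance to the remaining runs; ties go to the smallest index, and a
    single run is trivially selected.
    """
    M = len(Qs)
    if M == 0:
        raise ValueError("need at least one run")
    if M == 1:
        return 0
    dist = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            dist[i, j] = dist[j, i] = np.linalg.norm(Qs[i] - Qs[j], 2)
    medians = [np.median(np.delete(dist[m], m)) for m in range(M)]
    return int(np.argmin(medians))


def hierarchical_init(
    Z: np.ndarray,
    K: int,
    family: str = "unconstrained",
    y: np.ndarray | None = None,
) -> MixtureParams:
    """Initial parameters from Ward-linkage clustering cut at K clusters.

    If ``y`` is given and contains observed labels, clusters are numbered
    by the maximum-agreement assignment to those labels, so the initial
    class identities are consistent with the labels that the E step will
    pin.  Otherwise clusters are numbered by order of first appearance (a
    deterministic convention shared with the compiled ensemble path).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = fcluster(linkage(Z, method="ward"), K, criterion="maxclust")
    remap: dict[int, int] = {}
    renumbered = np.empty(labels.shape[0], dtype=int)
    for i, c in enumerate(labels):
        renumbered[i] = remap.setdefault(int(c), len(remap))
    if y is not None and (np.asarray(y) > 0).any():
        from scipy.optimize import linear_sum_assignment

        y = np.asarray(y).astype(int)
        agree = np.zeros((K, K))
        np.add.at(agree, (renumbered[y > 0], y[y > 0] - 1), 1.0)
        rows, cols = linear_sum_assignment(agree, maximize=True)
        perm = np.empty(K, dtype=int)
        perm[rows] = cols
        renumbered = perm[renumbered]
    L = np.zeros((Z.shape[0], K))
    L[np.arange(Z.shape[0]), renumbered] = 1.0
    return m_step(Z, L, family)


def sphere_init(
    d: int, rng: np.random.Generator, radius: float = 0.3
) -> MixtureParams:
    """Symmetric-family random initialisation on a sphere of given radius."""
    mu = rng.normal(size=d)
    mu *= radius / np.linalg.norm(mu)
    return MixtureParams(np.stack([-mu, mu]), np.eye(d))


InitPolicy = Callable[[np.ndarray, int, np.random.Generator], MixtureParams]


def em_importance(
    Z: np.ndarray,
    y: np.ndarray,
    K: int,
    family: str = "unconstrained",
    M: int = 1,
    T: int = 100,
    init_policy: str | InitPolicy = "hierarchical",
    rng: np.random.Generator | None = None,
    init_radius: float = 0.3,
    loglik_rtol: float | None = LOGLIK_RTOL,
) -> np.ndarray:
    """Importance scores from the EM base learner.

    For each of ``M`` restarts, runs EM and forms the whitened soft
    between-class covariance ``Q = Gw^{-1} Gb``; the most mutually
    consistent restart is selected and the (0-clipped) diagonal of its
    ``Q`` returned.  ``init_policy`` is ``"hierarchical"`` (Ward-linkage
    hard clustering; deterministic, so normally used with M=1),
    ``"random"`` (symmetric-family sphere initialisation of radius
    ``init_radius``), or a callable ``(Z, K, rng) -> MixtureParams``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if rng is None:
        rng = np.random.default_rng()
    Qs = []
    for _ in range(M):
        if init_policy == "hierarchical":
            init = hierarchical_init(Z, K, family)
        elif init_policy == "random":
            if family != "symmetric":
                raise ValueError(
                    "the sphere initialisation is defined for the symmetric family; "
                    "pass a callable init_policy for other families"
                )
            init = sphere_init(Z.shape[1], rng, init_radius)
        else:
            init = init_policy(Z, K, rng)
        params, L = run_em(Z, y, init, family, T, loglik_rtol=loglik_rtol)
        _, between = soft_between_covariance(L, params)
        Q = np.linalg.solve(params.within, between)
        Qs.append(Q)
    best = select_run(Qs)
    return np.clip(np.diag(Qs[best]), 0.0, None)
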