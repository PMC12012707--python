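"""Ensemble variable selection over axis-aligned random projections.

The selector draws A*B axis-aligned projections uniformly at random,
applies a permutation-equivariant base learner to each projected dataset
to obtain per-coordinate importance scores, keeps the highest-scoring
projection within each of the A groups (largest score sum, ties to the
smallest index), back-projects the winners' scores into the ambient
space, and averages them.  The selected variable set is the top-l
coordinates of the aggregated score vector.

Grouping matters: conditional on the data, the A chosen projections are
independent and identically distributed, which is what makes the
aggregated scores concentrate; selecting the A globally best projections
would break that independence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import base_em, base_labeled
from ._ensemble import ensemble_em_scores
from .errors import DegenerateDataError
from .projections import AxisAlignedProjection, sample_projection

logger = logging.getLogger(__name__)


def rayleigh_quotient(V: np.ndarray, Sb: np.ndarray, Sw: np.ndarray) -> float:
    """Generalised Rayleigh quotient tr{(V'Sw V)^{-1} (V'Sb V)}.

    Measures the class-distinguishing ability of the subspace spanned by
    the orthonormal columns of ``V``; it depends on ``V`` only through its
    column space.  The maximising subspace contains the eigenspace of the
    K-1 nonzero eigenvalues of ``Sw^{-1} Sb``.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.ndim != 2:
        raise ValueError("V must be a p x d matrix")
    d = V.shape[1]
    if not np.allclose(V.T @ V, np.eye(d), atol=1e-8):
        raise ValueError("columns of V must be orthonormal")
    num = V.T @ np.asarray(Sb) @ V
    den = V.T @ np.asarray(Sw) @ V
    try:
        sol = np.linalg.solve(den, num)
    except np.linalg.LinAlgError as err:
        raise DegenerateDataError("V'Sw V is singular") from err
    return float(np.trace(sol))


def group_select(scores: np.ndarray | list[np.ndarray]) -> int:
    """Index (0-based) of the score vector with the largest coordinate sum.

    Ties are broken toward the smallest index (deterministic sargmax).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.size == 0:
        raise ValueError("need at least one score vector")
    return int(np.argmax(scores.sum(axis=1)))


def aggregate(
    selected: list[tuple[AxisAlignedProjection, np.ndarray]], p: int | None = None
) -> np.ndarray:
    """Average of back-projected score vectors over the selected projections."""
    if not selected:
        raise ValueError("need at least one (projection, scores) pair")
    ps = {P.p for P, _ in selected}
    if len(ps) != 1:
        raise ValueError("projections disagree on the ambient dimension")
    if p is not None and ps != {p}:
        raise ValueError("projections disagree with the requested dimension p")
    w = np.zeros(ps.pop())
    for P, s in selected:
        w += P.backproject(s)
    return w / len(selected)


def top_l(w: np.ndarray, l: int) -> np.ndarray:
    """0-based indices of the l largest scores; ties go to smaller indices."""
    w = np.asarray(w, dtype=float).ravel()
    if not 1 <= l <= w.shape[0]:
        raise ValueError(f"need 1 <= l <= p, got l={l}, p={w.shape[0]}")
    return np.sort(np.argsort(-w, kind="stable")[:l])


@dataclass(frozen=True)
class SharpSSLConfig:
    """Configuration of the projection-ensemble selector.

    ``A`` groups of ``B`` projections into ``d`` dimensions; ``n_select``
    (the algorithm's "l") variables are returned.  ``base`` chooses the
    importance scorer: ``"labeled"`` (labeled-data moments, whitened
    between-class diagonal, constraint family ``family``) or ``"em"``
    (semi-supervised EM with ``M`` restarts, ``T`` iterations and
    ``init_policy``).  Defaults A=150, B=75 are the settings used for the
    simulation studies.
    """

    d: int
    n_select: int
    A: int = 150
    B: int = 75
    base: str = "em"
    family: str | None = None
    M: int = 1
    T: int = 100
    init_policy: str = "hierarchical"
    init_radius: float = 0.3
    loglik_rtol: float = base_em.LOGLIK_RTOL
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.A < 1 or self.B < 1:
            raise ValueError("need A >= 1 and B >= 1")
        if self.base not in ("labeled", "em"):
            raise ValueError("base must be 'labeled' or 'em'")
        if self.M < 1 or self.T < 1:
            raise ValueError("need M >= 1 and T >= 1")

    def base_family(self) -> str:
        if self.family is not None:
            return self.family
        return "diagonal" if self.base == "labeled" else "unconstrained"


@dataclass(frozen=True)
class SelectionResult:
    """Aggregated scores, selected variables and per-group diagnostics."""

    scores: np.ndarray  # (p,) aggregated nonnegative importance scores
    selected: np.ndarray  # (l,) 0-based variable indices, sorted
    group_projections: list[AxisAlignedProjection] = field(repr=False)
    group_scores: list[np.ndarray] = field(repr=False)

    def diagnostics(self) -> pd.DataFrame:
        """Per-group table: chosen projection (1-based indices), score sum."""
        rows = [
            {
                "group": a + 1,
                "indices": ",".join(str(i + 1) for i in P.indices),
                "score_sum": float(s.sum()),
            }
            for a, (P, s) in enumerate(zip(self.group_projections, self.group_scores))
        ]
        return pd.DataFrame(rows)


def _base_scorer(config: SharpSSLConfig, K: int):
    family = config.base_family()
    if config.base == "labeled":
        def scorer(Z, y, rng):
            return base_labeled.labeled_importance(Z, y, K, family)
    else:
        def scorer(Z, y, rng):
            return base_em.em_importance(
                Z,
                y,
                K,
                family=family,
                M=config.M,
                T=config.T,
                init_policy=config.init_policy,
                rng=rng,
                init_radius=config.init_radius,
                loglik_rtol=config.loglik_rtol,
            )
    return scorer


def sharp_ssl_select(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    config: SharpSSLConfig,
    fast: bool = True,
) -> SelectionResult:
    """Run the full ensemble selection.

    Each of the A*B cells gets an independent random stream spawned from
    ``config.seed``, used to sample its projection (and any base-learner
    randomness), so the result is reproducible and independent of
    evaluation order.  A base-learner failure on a single projection
    scores that projection 0 rather than aborting the ensemble.

    ``fast=True`` routes the common configuration (EM base, hierarchical
    initialisation, single restart) through a compiled kernel; the
    generic path is used otherwise and produces the same selections.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different lengths")
    if K < 2:
        raise ValueError("need K >= 2")
    if not 1 <= config.d <= min(p, n - K):
        raise ValueError(f"need 1 <= d <= min(p, n - K) = {min(p, n - K)}")
    if not 1 <= config.n_select <= p:
        raise ValueError("need 1 <= n_select <= p")

    A, B, d = config.A, config.B, config.d
    children = np.random.SeedSequence(config.seed).spawn(A * B)
    projections = [
        sample_projection(p, d, np.random.default_rng(children[c]))
        for c in range(A * B)
    ]

    use_kernel = (
        fast
        and config.base == "em"
        and config.init_policy == "hierarchical"
        and config.M == 1
        and config.base_family() == "unconstrained"
    )
    if use_kernel:
        P = np.asarray([proj.indices for proj in projections], dtype=np.int64)
        all_scores = ensemble_em_scores(
            X, y.astype(np.int64), P, K, config.T, base_em.PARAM_TOL,
            config.loglik_rtol,
        )
    else:
        scorer = _base_scorer(config, K)
        all_scores = np.zeros((A * B, d))
        for c, proj in enumerate(projections):
            rng = np.random.default_rng(children[c])
            rng.choice(p, size=d, replace=False)  # advance past the projection draw
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    all_scores[c] = scorer(proj.project(X), y, rng)
            except DegenerateDataError as err:
                logger.warning(
                    "base learner failed on projection %d (%s); scoring 0", c, err
                )

    chosen: list[tuple[AxisAlignedProjection, np.ndarray]] = []
    log_every = max(1, A // 10)
    for a in range(A):
        block = all_scores[a * B : (a + 1) * B]
        b_star = group_select(block)
        chosen.append((projections[a * B + b_star], block[b_star]))
        if (a + 1) % log_every == 0:
            logger.info("processed %d/%d projection groups", a + 1, A)

    w = aggregate(chosen, p)
    selected = top_l(w, config.n_select)
    return SelectionResult(
        scores=w,
        selected=selected,
        group_projections=[P for P, _ in chosen],
        group_scores=[s for _, s in chosen],
    )
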