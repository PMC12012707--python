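"""Axis-aligned projections.

An axis-aligned projection is a binary ``d x p`` matrix with orthonormal
rows: applying it to a vector simply selects ``d`` of its ``p`` coordinates.
We never materialise the matrix; a projection is stored as an ordered list
of distinct column indices.  Indices are 0-based internally; user-facing
output (selected-variable reports) is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AxisAlignedProjection:
    """An ordered selection of ``d`` distinct coordinates out of ``p``.

    Parameters
    ----------
    indices
        Tuple of distinct 0-based coordinate indices, one per projected
        dimension, in order.
    p
        Ambient dimension.
    """

    indices: tuple[int, ...]
    p: int

    def __post_init__(self) -> None:
        d = len(self.indices)
        if not 1 <= d <= self.p:
            raise ValueError(f"need 1 <= d <= p, got d={d}, p={self.p}")
        if len(set(self.indices)) != d:
            raise ValueError("projection indices must be distinct")
        if min(self.indices) < 0 or max(self.indices) >= self.p:
            raise ValueError("projection indices out of range [0, p)")

    @property
    def d(self) -> int:
        return len(self.indices)

    def project(self, X: np.ndarray) -> np.ndarray:
        """Select the projection's coordinates (columns) of ``X``."""
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.p:
            raise ValueError(
                f"X has {X.shape[1]} columns but projection expects p={self.p}"
            )
        return X[:, list(self.indices)]

    def backproject(self, w: np.ndarray) -> np.ndarray:
        """Scatter a length-``d`` vector back into ambient dimension ``p``.

        The result has ``w[j]`` at position ``indices[j]`` and zeros
        elsewhere, so ``project(backproject(w))`` is the identity on ``w``.
        """
        w = np.asarray(w, dtype=float).ravel()
        if w.shape[0] != self.d:
            raise ValueError(f"w has length {w.shape[0]}, expected d={self.d}")
        out = np.zeros(self.p)
        out[list(self.indices)] = w
        return out


def sample_projection(
    p: int, d: int, rng: np.random.Generator
) -> AxisAlignedProjection:
    """Draw a projection uniformly at random from the axis-aligned set.

    Every size-``d`` subset of the ``p`` coordinates is equally likely;
    the within-projection order is a uniform random permutation (the base
    learners are permutation equivariant, so order is immaterial).
    """
    if not 1 <= d <= p:
        raise ValueError(f"need 1 <= d <= p, got d={d}, p={p}")
    idx = rng.choice(p, size=d, replace=False)
    return AxisAlignedProjection(tuple(int(i) for i in idx), p)


def project(X: np.ndarray, P: AxisAlignedProjection) -> np.ndarray:
    """Functional form of :meth:`AxisAlignedProjection.project`."""
    return P.project(X)


def backproject(w: np.ndarray, P: AxisAlignedProjection) -> np.ndarray:
    """Functional form of :meth:`AxisAlignedProjection.backproject`."""
    return P.backproject(w)
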