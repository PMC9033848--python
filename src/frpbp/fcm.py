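"""Fuzzy c-means clustering of phase-space states.

FCM partitions the N embedded states into ``c`` overlapping clusters by
minimising

    J(U, Z) = sum_i sum_k mu_{i,k}^omega * ||x_i - z_k||^2,
    subject to sum_k mu_{i,k} = 1,

where ``omega > 1`` is the fuzzy weighting exponent (2 throughout this
package). Minimisation alternates the closed-form membership update

    mu_{i,k} = 1 / sum_j (d(x_i, z_k) / d(x_i, z_j))^(2/(omega-1))

with the weighted-mean center update

    z_j = sum_i mu_{i,j}^omega x_i / sum_i mu_{i,j}^omega,

until the membership matrix stops moving (max |U(t) - U(t+1)| <= alpha) or an
iteration cap is hit. A state coinciding with a center receives crisp
membership there (lowest cluster index on ties). The resulting membership
matrix is what the fuzzy recurrence plot is composed from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FuzzyPartition",
    "DegenerateClusterError",
    "fcm_objective",
    "update_memberships",
    "update_centers",
    "fcm_fit",
]

DEFAULT_OMEGA = 2.0
DEFAULT_ALPHA = 1e-5
DEFAULT_MAX_ITER = 300


class DegenerateClusterError(ValueError):
    """A cluster received zero total membership, so its center is undefined."""


@dataclass(frozen=True)
class FuzzyPartition:
    """FCM output: memberships ``U`` (N x c), centers ``Z`` (c x d)."""

    U: np.ndarray
    Z: np.ndarray
    c: int
    omega: float
    alpha: float
    J: float
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False
    J_history: tuple = ()  # objective after each center+membership update

    def __post_init__(self) -> None:
        u = np.asarray(self.U, dtype=float)
        z = np.asarray(self.Z, dtype=float)
        if u.ndim != 2 or u.shape[1] != self.c:
            raise ValueError("U must be an (N, c) matrix")
        if z.ndim != 2 or z.shape[0] != self.c:
            raise ValueError("Z must hold c centers")
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        object.__setattr__(self, "U", u)
        object.__setattr__(self, "Z", z)


def _as_states(states: np.ndarray) -> np.ndarray:
    x = np.asarray(states, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("states must be an (N, d) array")
    return x


def fcm_objective(states: np.ndarray, U: np.ndarray, Z: np.ndarray, omega: float) -> float:
    """Weighted within-cluster squared scatter J(U, Z)."""
    if not omega > 1:
        raise ValueError(f"fuzzy weighting exponent must exceed 1, got {omega}")
    x = _as_states(states)
    u = np.asarray(U, dtype=float)
    z = _as_states(Z)
    if u.shape != (x.shape[0], z.shape[0]):
        raise ValueError(f"U shape {u.shape} inconsistent with N={x.shape[0]}, c={z.shape[0]}")
    d2 = cdist(x, z, metric="sqeuclidean")
    return float(np.sum(u**omega * d2))


def update_memberships(states: np.ndarray, Z: np.ndarray, omega: float) -> np.ndarray:
    """Closed-form membership update from current centers."""
    if not omega > 1:
        raise ValueError(f"fuzzy weighting exponent must exceed 1, got {omega}")
    x = _as_states(states)
    z = _as_states(Z)
    if z.shape[0] < 1:
        raise ValueError("need at least one cluster center")
    d = cdist(x, z)
    # exact coincidence up to float rounding counts as zero distance
    tol = 1e-12 * max(1.0, float(np.max(np.abs(x), initial=0.0)))
    zero_rows = np.min(d, axis=1) <= tol
    power = 2.0 / (omega - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        for i in np.flatnonzero(zero_rows):
            u[i] = 0.0
            u[i, int(np.argmax(d[i] <= tol))] = 1.0  # first zero-distance cluster
    return u


def update_centers(states: np.ndarray, U: np.ndarray, omega: float) -> np.ndarray:
    """Membership-weighted mean update of the cluster centers."""
    if not omega > 1:
        raise ValueError(f"fuzzy weighting exponent must exceed 1, got {omega}")
    x = _as_states(states)
    u = np.asarray(U, dtype=float)
    if u.ndim != 2 or u.shape[0] != x.shape[0]:
        raise ValueError("U must have one row per state")
    w = u**omega
    totals = w.sum(axis=0)
    if np.any(totals <= 0.0):
        bad = np.flatnonzero(totals <= 0.0).tolist()
        raise DegenerateClusterError(
            f"cluster(s) {bad} have zero total membership; centers undefined"
        )
    return (w.T @ x) / totals[:, None]


def fcm_fit(
    states: np.ndarray,
    c: int = 3,
    omega: float = DEFAULT_OMEGA,
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | np.random.Generator = 0,
) -> FuzzyPartition:
    """Run FCM from a seeded random row-stochastic membership matrix.

    Alternates center and membership updates until the elementwise change of
    ``U`` falls to ``alpha`` or ``max_iter`` is reached (the latter sets
    ``converged=False`` on the result rather than raising). Clusters emptied
    by a crisp zero-distance assignment keep their previous center and flag
    the partition ``degenerate`` — this happens for e.g. constant segments
    where every state coincides.
    """
    x = _as_states(states)
    n = x.shape[0]
    if c < 1:
        raise ValueError("need at least one cluster")
    if n < c:
        raise ValueError(f"cannot form c={c} clusters from N={n} states")
    if not alpha > 0:
        raise ValueError("stopping tolerance alpha must be positive")
    if not omega > 1:
        raise ValueError(f"fuzzy weighting exponent must exceed 1, got {omega}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    z = np.zeros((c, x.shape[1]))
    degenerate = False
    converged = False
    n_iter = 0
    j_history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        w = u**omega
        totals = w.sum(axis=0)
        alive = totals > 0.0
        if not np.all(alive):
            degenerate = True
        z[alive] = (w[:, alive].T @ x) / totals[alive, None]
        u_new = update_memberships(x, z, omega)
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        j_history.append(fcm_objective(x, u, z, omega))
        if delta <= alpha:
            converged = True
            break

    return FuzzyPartition(
        U=u, Z=z, c=c, omega=omega, alpha=alpha, J=j_history[-1],
        n_iter=n_iter, converged=converged, degenerate=degenerate,
        J_history=tuple(j_history),
    )
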