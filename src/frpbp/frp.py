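"""Binary and fuzzy recurrence plots.

A recurrence plot (RP) marks which pairs of phase-space states are closer
than a threshold ``epsilon``: ``R_ij = 1`` iff ``||r_i - r_j||_2 < epsilon``.
Its fuzzy counterpart (FRP) drops the threshold entirely: states are fuzzy
c-means clustered, and the similarity of states ``i`` and ``j`` is inferred
through the max-min composition of the state-to-cluster fuzzy relation,

    M_ij = max_k min(mu_{i,k}, mu_{j,k}),

with reflexivity (``M_ii = 1``) imposed as an axiom and symmetry holding by
construction. The result is a grayscale, threshold-free similarity image of
the trajectory whose texture encodes the waveform's pseudo-periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .fcm import FuzzyPartition, fcm_fit, DEFAULT_ALPHA, DEFAULT_MAX_ITER, DEFAULT_OMEGA
from .phase_space import Segment, Trajectory, decimate_trajectory, embed

__all__ = [
    "RPMatrix",
    "FRPMatrix",
    "binary_rp",
    "fuzzy_rp",
    "frp_image",
    "save_frp_png",
    "load_frp_png",
    "segment_to_frp",
]


@dataclass(frozen=True)
class RPMatrix:
    """Binary N x N recurrence matrix with its threshold."""

    R: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        r = np.asarray(self.R)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("R must be square")
        object.__setattr__(self, "R", r.astype(np.uint8))


@dataclass(frozen=True)
class FRPMatrix:
    """Symmetric N x N fuzzy-similarity matrix, unit diagonal, values in [0,1]."""

    M: np.ndarray
    cluster_count: int

    def __post_init__(self) -> None:
        m = np.asarray(self.M, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("M must be square")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("FRP entries must lie in [0, 1]")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("FRP must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("FRP diagonal must be exactly 1")
        object.__setattr__(self, "M", m)

    @property
    def side(self) -> int:
        return self.M.shape[0]


def binary_rp(traj: Trajectory, epsilon: float) -> RPMatrix:
    """Threshold the pairwise state distances: ``R_ij = 1`` iff distance < epsilon."""
    if not epsilon > 0:
        raise ValueError(f"similarity threshold must be positive, got {epsilon}")
    d = squareform(pdist(traj.states))
    return RPMatrix(R=(d < epsilon).astype(np.uint8), epsilon=epsilon)


def fuzzy_rp(partition: FuzzyPartition) -> FRPMatrix:
    """Compose the FRP from FCM memberships by max-min composition."""
    u = partition.U
    # max over k of min(mu_ik, mu_jk), vectorised one row of clusters at a time
    n = u.shape[0]
    m = np.zeros((n, n))
    for k in range(u.shape[1]):
        col = u[:, k]
        np.maximum(m, np.minimum.outer(col, col), out=m)
    np.fill_diagonal(m, 1.0)  # reflexivity is axiomatic, not derived
    m = np.clip(m, 0.0, 1.0)
    m = 0.5 * (m + m.T)
    return FRPMatrix(M=m, cluster_count=partition.c)


def frp_image(frp: FRPMatrix, invert: bool = False) -> np.ndarray:
    """Return the FRP as a grayscale image array in [0, 1].

    ``invert=True`` returns ``1 - M`` for white-background rendering; the
    network consumes the un-inverted matrix.
    """
    return 1.0 - frp.M if invert else frp.M.copy()


def save_frp_png(frp: FRPMatrix, path, invert: bool = False) -> None:
    """Export as an 8-bit grayscale PNG (linear scaling to 0-255)."""
    from PIL import Image

    img = frp_image(frp, invert=invert)
    Image.fromarray(np.round(img * 255.0).astype(np.uint8), mode="L").save(path)


def load_frp_png(path) -> np.ndarray:
    """Read an exported plot back as a float array in [0, 1]."""
    from PIL import Image

    return np.asarray(Image.open(path), dtype=float) / 255.0


def segment_to_frp(
    segment: Segment,
    m_e: int = 3,
    tau: int = 5,
    side: int = 88,
    c: int = 3,
    omega: float = DEFAULT_OMEGA,
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | np.random.Generator = 0,
) -> FRPMatrix:
    """Full segment -> FRP pipeline: embed, decimate to ``side`` states, FCM, compose.

    Deterministic for a fixed seed.
    """
    traj = embed(segment, m_e=m_e, tau=tau)
    traj = decimate_trajectory(traj, side)
    part = fcm_fit(traj.states, c=c, omega=omega, alpha=alpha, max_iter=max_iter, seed=seed)
    return fuzzy_rp(part)
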