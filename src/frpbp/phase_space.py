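"""Phase-space reconstruction of pulse-waveform segments.

A scalar PPG window is lifted into state space by Takens delay embedding:
state ``p`` is the vector ``(x_p, x_{p+tau}, ..., x_{p+(m_e-1) tau})``. The
resulting trajectory of ``N = L - (m_e - 1) * tau`` states is the object the
recurrence plots are built from. Because the recurrence plot side length is a
modelling parameter (88 by default) rather than a consequence of the window
length, trajectories are decimated to a fixed number of states by uniform
index selection, which keeps the plot a genuine state-similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "Trajectory",
    "SegmentTooShortError",
    "embed",
    "decimate_trajectory",
]


class SegmentTooShortError(ValueError):
    """Raised when a segment cannot support the requested embedding."""


@dataclass(frozen=True)
class Segment:
    """A fixed-length window of a pulse waveform with scalar BP targets.

    Parameters
    ----------
    samples : ndarray
        Waveform amplitudes (arbitrary units).
    fs : float
        Sampling rate in Hz.
    sbp, dbp : float or None
        Systolic / diastolic pressure targets in mmHg for this window.
    """

    samples: np.ndarray
    fs: float = 125.0
    sbp: float | None = None
    dbp: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("segment needs a 1-D array of at least 2 samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.sbp is not None and self.dbp is not None and not self.sbp > self.dbp:
            raise ValueError(
                f"systolic pressure must exceed diastolic (got sbp={self.sbp}, dbp={self.dbp})"
            )
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Trajectory:
    """Ordered phase-space states reconstructed from one segment."""

    states: np.ndarray  # (N, m_e), temporal order preserved
    m_e: int
    tau: int

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        if states.ndim != 2 or states.shape[1] != self.m_e:
            raise ValueError("states must be an (N, m_e) array")
        object.__setattr__(self, "states", states)

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def __len__(self) -> int:
        return self.n_states


def embed(segment: Segment | np.ndarray, m_e: int = 3, tau: int = 5) -> Trajectory:
    """Delay-embed a segment into an ``(N, m_e)`` trajectory.

    ``N = L - (m_e - 1) * tau``; state ``p`` collects the samples
    ``x_p, x_{p+tau}, ..., x_{p+(m_e-1) tau}``.

    Raises
    ------
    SegmentTooShortError
        If ``L < (m_e - 1) * tau + 1``.
    """
    x = segment.samples if isinstance(segment, Segment) else np.asarray(segment, dtype=float)
    if m_e < 1 or tau < 1:
        raise ValueError(f"need m_e >= 1 and tau >= 1, got m_e={m_e}, tau={tau}")
    length = x.size
    min_len = (m_e - 1) * tau + 1
    if length < min_len:
        raise SegmentTooShortError(
            f"segment of length {length} too short for (m_e={m_e}, tau={tau}); "
            f"need at least {min_len} samples"
        )
    n = length - (m_e - 1) * tau
    cols = [x[i * tau : i * tau + n] for i in range(m_e)]
    return Trajectory(states=np.stack(cols, axis=1), m_e=m_e, tau=tau)


def _decimation_indices(n: int, s: int) -> np.ndarray:
    # round-half-up of linspace over 1..n, converted to 0-based indices
    grid = np.linspace(1.0, float(n), s)
    return np.floor(grid + 0.5).astype(int) - 1


def decimate_trajectory(traj: Trajectory, s: int) -> Trajectory:
    """Reduce a trajectory to exactly ``s`` states at uniformly spaced indices.

    The first and last states are always retained; ``s == N`` returns the
    trajectory unchanged.
    """
    n = traj.n_states
    if s < 2:
        raise ValueError(f"need at least 2 states after decimation, got S={s}")
    if s > n:
        raise ValueError(
            f"cannot decimate a trajectory of {n} states to S={s}; "
            "use a longer segment or a smaller S"
        )
    if s == n:
        return traj
    idx = _decimation_indices(n, s)
    return Trajectory(states=traj.states[idx], m_e=traj.m_e, tau=traj.tau)
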