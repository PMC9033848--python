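"""Regression metric suite for paired BP targets and estimates.

With errors ``e_i = Y_i - Yhat_i`` the report carries

    MAE = mean |e|            MSE = mean e^2        ME = mean e
    R^2 = 1 - SSres / SStot   R   = Pearson(Y, Yhat)
    STD = population standard deviation of e,

so the identity ``MSE = STD^2 + ME^2`` holds exactly. ``R`` (and ``R^2`` for
a constant target) is reported as undefined — never silently zero — when a
vector is constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    mae: float  # mmHg
    mse: float  # mmHg^2
    me: float  # mmHg
    r2: float  # dimensionless; nan when undefined
    r: float  # dimensionless; nan when undefined
    std: float  # mmHg, population std of the errors
    n: int
    r_defined: bool = True
    r2_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "me": self.me,
            "r2": self.r2 if self.r2_defined else None,
            "r": self.r if self.r_defined else None,
            "std": self.std,
            "n": self.n,
            "r_defined": self.r_defined,
            "r2_defined": self.r2_defined,
        }


def compute_metrics(y, yhat) -> MetricsReport:
    """Evaluate the six-metric suite on paired vectors (mmHg)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"y and yhat must be equal-length 1-D vectors, got {y.shape} vs {yhat.shape}")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("inputs must be finite")

    e = y - yhat
    mae = float(np.mean(np.abs(e)))
    mse = float(np.mean(e**2))
    me = float(np.mean(e))
    std = float(np.std(e))  # population convention (divisor n)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_defined = ss_tot > 0.0
    r2 = 1.0 - float(np.sum(e**2)) / ss_tot if r2_defined else math.nan

    r_defined = ss_tot > 0.0 and float(np.sum((yhat - yhat.mean()) ** 2)) > 0.0
    if r_defined:
        r = float(np.corrcoef(y, yhat)[0, 1])
    else:
        r = math.nan

    return MetricsReport(
        mae=mae, mse=mse, me=me, r2=r2, r=r, std=std, n=n,
        r_defined=r_defined, r2_defined=r2_defined,
    )
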