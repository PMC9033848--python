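"""Model/Results interface for cuffless BP estimation.

``FRPRegression`` bundles the full pipeline behind a statsmodels-style
surface: construct it from segmented records (or straight from the synthetic
generator), call :meth:`fit`, and receive an :class:`FRPRegressionResults`
carrying held-out predictions, the six-metric suite, BHS grade, AAMI verdict,
Bland-Altman agreement, the training history and a ``summary()`` table.

Example
-------
>>> from frpbp import FRPRegression
>>> model = FRPRegression.from_generator(n_records=4, duration=120, target="sbp", seed=0)
>>> res = model.fit(max_epochs=5)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .frp import segment_to_frp
from .metrics import MetricsReport, compute_metrics
from .models import (
    ModelConfig,
    TrainConfig,
    TwoStreamRegressor,
    build_concat_model,
    train_model,
)
from .phase_space import Segment
from .standards_eval import (
    AAMIResult,
    BHSResult,
    BlandAltman,
    aami_check,
    bhs_evaluate,
    bland_altman,
)
from .synthetic_data import GeneratorConfig, generate_records, segment_record, split_segments

__all__ = ["FRPConfig", "FRPRegression", "FRPRegressionResults"]


@dataclass(frozen=True)
class FRPConfig:
    """Embedding + clustering parameters for the fuzzy recurrence plots."""

    m_e: int = 3  # embedding dimension
    tau: int = 5  # embedding delay in samples (40 ms at 125 Hz)
    c: int = 3  # fuzzy clusters
    omega: float = 2.0  # fuzzy weighting exponent
    alpha: float = 1e-5  # FCM stopping tolerance
    side: int = 88  # plot side length (states after decimation)


class FRPRegression:
    """Two-stream CNN regression of blood pressure from PPG segments.

    Parameters
    ----------
    segments_per_record : list of list of Segment
        Windows grouped by source record; the chronological 70/10/20 split
        is applied within each record.
    target : {"sbp", "dbp"}
    model_config : ModelConfig, optional
        Architecture; defaults to :meth:`ModelConfig.small` resized to the
        segment window and FRP side.
    frp_config : FRPConfig, optional
    seed : int
        Seeds FCM initialisation, weight init, dropout and batch order.
    """

    def __init__(
        self,
        segments_per_record: list[list[Segment]],
        target: str = "sbp",
        model_config: ModelConfig | None = None,
        frp_config: FRPConfig | None = None,
        split: tuple[float, float, float] = (0.7, 0.1, 0.2),
        seed: int = 0,
    ):
        if target not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")
        if not segments_per_record or not any(segments_per_record):
            raise ValueError("need at least one record with segments")
        window = len(segments_per_record[0][0])
        self.frp_config = frp_config or FRPConfig(side=32)
        if model_config is None:
            model_config = replace(ModelConfig.small(target), window=window,
                                   side=self.frp_config.side)
        if model_config.side != self.frp_config.side:
            raise ValueError("model side and FRP side must agree")
        self.segments_per_record = segments_per_record
        self.target = target
        self.model_config = replace(model_config, target=target)
        self.split = split
        self.seed = seed
        self._frp_cache: dict[str, np.ndarray] | None = None

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_records(cls, records, window: int = 512, stride: int | None = None, **kwargs):
        segs = [segment_record(r, window=window, stride=stride) for r in records]
        return cls([s for s in segs if s], **kwargs)

    @classmethod
    def from_generator(
        cls,
        n_records: int = 4,
        duration: float = 120.0,
        window: int = 512,
        generator_config: GeneratorConfig | None = None,
        seed: int = 0,
        **kwargs,
    ):
        cfg = generator_config or GeneratorConfig(duration=duration, seed=seed)
        records = generate_records(cfg, n_records, seed=seed)
        return cls.from_records(records, window=window, seed=seed, **kwargs)

    # -- pipeline ------------------------------------------------------------
    def _segment_frp(self, segment: Segment) -> np.ndarray:
        f = self.frp_config
        return segment_to_frp(
            segment, m_e=f.m_e, tau=f.tau, side=f.side, c=f.c,
            omega=f.omega, alpha=f.alpha, seed=self.seed,
        ).M

    def build_dataset(self):
        """FRPs + arrays for the three chronological splits (cached)."""
        train, val, test = split_segments(self.segments_per_record, self.split)

        def pack(segs):
            x1 = np.stack([s.samples for s in segs])
            x2 = np.stack([self._segment_frp(s) for s in segs])
            y = np.array([getattr(s, self.target) for s in segs], dtype=float)
            return x1, x2, y

        if self._frp_cache is None:
            self._frp_cache = {"train": pack(train), "val": pack(val), "test": pack(test)}
        return self._frp_cache["train"], self._frp_cache["val"], self._frp_cache["test"]

    def fit(
        self,
        batch: int = 100,
        lr: float = 1e-3,
        max_epochs: int = 300,
        patience: int = 30,
        verbose: bool = False,
    ) -> "FRPRegressionResults":
        """Train the concatenated two-stream network; evaluate on the test split."""
        train, val, test = self.build_dataset()
        spec = build_concat_model(self.model_config)
        hyper = TrainConfig(batch=batch, lr=lr, max_epochs=max_epochs,
                            patience=patience, seed=self.seed)
        network, history = train_model(spec, train, val, hyper, verbose=verbose)
        y_test = test[2]
        yhat = network.predict(test[0], test[1])
        return FRPRegressionResults(self, network, history, y_test, yhat)

    def baseline_mae(self) -> float:
        """MAE of the constant training-mean predictor on the test split."""
        train, _, test = self.build_dataset()
        return float(np.mean(np.abs(test[2] - train[2].mean())))


class FRPRegressionResults:
    """Fitted-model container: predictions, metrics, standards, history."""

    def __init__(self, model: FRPRegression, network: TwoStreamRegressor,
                 history: list[dict], y_test: np.ndarray, yhat_test: np.ndarray):
        self.model = model
        self.network = network
        self.history = history
        self.y_test = np.asarray(y_test, dtype=float)
        self.yhat_test = np.asarray(yhat_test, dtype=float)
        self._metrics: MetricsReport | None = None

    # -- derived quantities --------------------------------------------------
    @property
    def errors(self) -> np.ndarray:
        return self.y_test - self.yhat_test

    @property
    def metrics(self) -> MetricsReport:
        if self._metrics is None:
            self._metrics = compute_metrics(self.y_test, self.yhat_test)
        return self._metrics

    @property
    def bhs(self) -> BHSResult:
        return bhs_evaluate(self.errors)

    def aami(self, subjects: int | None = None) -> AAMIResult:
        m = self.metrics
        n_subj = subjects if subjects is not None else len(self.model.segments_per_record)
        return aami_check(m.me, m.std, n_subj)

    @property
    def bland_altman(self) -> BlandAltman:
        return bland_altman(self.y_test, self.yhat_test)

    def predict(self, segments: list[Segment]) -> np.ndarray:
        x1 = np.stack([s.samples for s in segments])
        x2 = np.stack([self.model._segment_frp(s) for s in segments])
        return self.network.predict(x1, x2)

    def to_dict(self) -> dict:
        m, b, ba = self.metrics, self.bhs, self.bland_altman
        a = self.aami()
        return {
            "target": self.model.target,
            "n_test": m.n,
            "metrics": m.to_dict(),
            "bhs": {"cum5": b.cum5, "cum10": b.cum10, "cum15": b.cum15, "grade": b.grade},
            "aami": {"me": a.me, "std": a.std, "subjects": a.subjects,
                     "pass": a.passed, "reasons": list(a.reasons)},
            "bland_altman": {"bias": ba.bias, "loa_low": ba.loa_low,
                             "loa_high": ba.loa_high, "within_fraction": ba.within_fraction},
            "epochs_trained": len(self.history),
        }

    def summary(self) -> str:
        m, b, ba = self.metrics, self.bhs, self.bland_altman
        a = self.aami()
        t = self.model.target.upper()
        lines = [
            f"{'':=^62}",
            f"{' FRP two-stream regression — ' + t + ' ':^62}",
            f"{'':=^62}",
            f"test segments       {m.n:>10d}    epochs trained {len(self.history):>7d}",
            f"MAE   {m.mae:10.3f} mmHg     MSE  {m.mse:10.3f} mmHg^2",
            f"ME    {m.me:10.3f} mmHg     STD  {m.std:10.3f} mmHg",
            f"R^2   {m.r2 if m.r2_defined else float('nan'):10.3f}          "
            f"R    {m.r if m.r_defined else float('nan'):10.3f}",
            f"{'-':-^62}",
            f"BHS   <=5: {b.cum5:6.2f}%  <=10: {b.cum10:6.2f}%  <=15: {b.cum15:6.2f}%  grade {b.grade}",
            f"AAMI  {'PASS' if a.passed else 'FAIL'}"
            + ("" if a.passed else "  (" + "; ".join(a.reasons) + ")"),
            f"Bland-Altman  bias {ba.bias:7.3f}  LoA [{ba.loa_low:7.3f}, {ba.loa_high:7.3f}]"
            f"  within {100 * ba.within_fraction:5.1f}%",
            f"{'':=^62}",
        ]
        return "\n".join(lines)
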