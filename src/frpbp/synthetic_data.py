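"""Synthetic pseudo-periodic PPG-like records with BP-dependent morphology.

Each beat is a two-Gaussian template: a systolic wave whose amplitude

    A1 = a0 + a1 * (SBP - 120) / 40

tracks systolic pressure, and a dicrotic/diastolic wave whose amplitude

    A2 = b0 + b1 * (DBP - 80) / 30

tracks diastolic pressure. Beat period is 60/HR seconds with per-beat HR
jitter; SBP and DBP follow bounded random walks sampled once per beat;
additive white Gaussian noise and a sinusoidal baseline wander complete the
signal. Per-sample SBP/DBP label series are emitted alongside the waveform,
so fixed windows carry the mean label of the samples they cover.

The coupling between pressure and pulse morphology is a deliberate idealised
stand-in for real photoplethysmography — it makes the targets recoverable in
principle so that every downstream stage is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .phase_space import Segment

__all__ = [
    "GeneratorConfig",
    "SignalRecord",
    "generate_record",
    "generate_records",
    "segment_record",
    "split_segments",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic record."""

    fs: float = 125.0  # Hz
    duration: float = 60.0  # s
    hr_mean: float = 75.0  # bpm
    hr_sd: float = 3.0  # bpm, per-beat jitter
    sbp_start: float = 120.0  # mmHg
    sbp_step_sd: float = 1.5  # mmHg per beat
    sbp_bounds: tuple[float, float] = (90.0, 180.0)
    dbp_start: float = 80.0
    dbp_step_sd: float = 1.0
    dbp_bounds: tuple[float, float] = (50.0, 110.0)
    noise_sd: float = 0.02  # amplitude units
    wander_amp: float = 0.1  # amplitude units
    wander_freq: float = 0.2  # Hz
    # BP -> morphology coupling
    a0: float = 1.0
    a1: float = 0.5
    b0: float = 0.4
    b1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.hr_sd, self.sbp_step_sd, self.dbp_step_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (self.sbp_bounds[0] < self.sbp_bounds[1] and self.dbp_bounds[0] < self.dbp_bounds[1]):
            raise ValueError("bounds must be (low, high) with low < high")
        if not self.sbp_bounds[0] > self.dbp_bounds[0] or not self.sbp_bounds[1] > self.dbp_bounds[1]:
            raise ValueError("systolic bounds must sit strictly above diastolic bounds")
        if not (self.sbp_bounds[0] <= self.sbp_start <= self.sbp_bounds[1]):
            raise ValueError("sbp_start outside its bounds")
        if not (self.dbp_bounds[0] <= self.dbp_start <= self.dbp_bounds[1]):
            raise ValueError("dbp_start outside its bounds")


@dataclass(frozen=True)
class SignalRecord:
    """A sampled waveform with aligned per-sample SBP/DBP target series."""

    ppg: np.ndarray
    fs: float
    sbp: np.ndarray
    dbp: np.ndarray
    record_id: str = "rec"

    def __post_init__(self) -> None:
        ppg = np.asarray(self.ppg, dtype=float)
        sbp = np.asarray(self.sbp, dtype=float)
        dbp = np.asarray(self.dbp, dtype=float)
        if not (ppg.shape == sbp.shape == dbp.shape) or ppg.ndim != 1:
            raise ValueError("ppg, sbp and dbp must be aligned 1-D arrays")
        for name, arr in (("ppg", ppg), ("sbp", sbp), ("dbp", dbp)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.ppg.size


def _beat_template(n: int, a1: float, a2: float) -> np.ndarray:
    """One beat of ``n`` samples: systolic + dicrotic Gaussian waves."""
    phase = np.arange(n) / n
    sys_wave = a1 * np.exp(-0.5 * ((phase - 0.30) / 0.10) ** 2)
    dic_wave = a2 * np.exp(-0.5 * ((phase - 0.65) / 0.15) ** 2)
    return sys_wave + dic_wave


def generate_record(cfg: GeneratorConfig, record_id: str = "rec") -> SignalRecord:
    """Synthesize one record; bitwise reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    total = int(round(cfg.duration * cfg.fs))

    ppg_parts: list[np.ndarray] = []
    sbp_parts: list[np.ndarray] = []
    dbp_parts: list[np.ndarray] = []
    sbp, dbp = cfg.sbp_start, cfg.dbp_start
    n_done = 0
    while n_done < total:
        hr = cfg.hr_mean + (rng.normal(0.0, cfg.hr_sd) if cfg.hr_sd > 0 else 0.0)
        hr = max(hr, 20.0)
        n_beat = max(int(round(cfg.fs * 60.0 / hr)), 2)
        amp_sys = cfg.a0 + cfg.a1 * (sbp - 120.0) / 40.0
        amp_dic = cfg.b0 + cfg.b1 * (dbp - 80.0) / 30.0
        ppg_parts.append(_beat_template(n_beat, amp_sys, amp_dic))
        sbp_parts.append(np.full(n_beat, sbp))
        dbp_parts.append(np.full(n_beat, dbp))
        n_done += n_beat
        # per-beat bounded random walk (reflected at the bounds); keep a
        # physiological pulse pressure of at least 10 mmHg
        if cfg.sbp_step_sd > 0:
            sbp = _reflect(sbp + rng.normal(0.0, cfg.sbp_step_sd), *cfg.sbp_bounds)
        if cfg.dbp_step_sd > 0:
            dbp = _reflect(dbp + rng.normal(0.0, cfg.dbp_step_sd), *cfg.dbp_bounds)
        if sbp < dbp + 10.0:
            sbp = min(dbp + 10.0, cfg.sbp_bounds[1])

    ppg = np.concatenate(ppg_parts)[:total]
    sbp_series = np.concatenate(sbp_parts)[:total]
    dbp_series = np.concatenate(dbp_parts)[:total]

    t = np.arange(total) / cfg.fs
    if cfg.wander_amp > 0:
        ppg = ppg + cfg.wander_amp * np.sin(2.0 * np.pi * cfg.wander_freq * t)
    if cfg.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, cfg.noise_sd, size=total)

    return SignalRecord(ppg=ppg, fs=cfg.fs, sbp=sbp_series, dbp=dbp_series, record_id=record_id)


def _reflect(value: float, low: float, high: float) -> float:
    span = high - low
    v = (value - low) % (2.0 * span)
    return low + (v if v <= span else 2.0 * span - v)


def generate_records(cfg: GeneratorConfig, n_records: int, seed: int | None = None) -> list[SignalRecord]:
    """Generate ``n_records`` independent records with per-record derived seeds."""
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    children = ss.spawn(n_records)
    out = []
    for i, child in enumerate(children):
        sub = int(child.generate_state(1)[0] % (2**31))
        rec_cfg = GeneratorConfig(**{**asdict(cfg), "seed": sub})
        out.append(generate_record(rec_cfg, record_id=f"rec{i:03d}"))
    return out


def segment_record(record: SignalRecord, window: int = 1024, stride: int | None = None) -> list[Segment]:
    """Cut a record into fixed windows; labels are the window means."""
    if stride is None:
        stride = window
    if window < 2 or stride < 1:
        raise ValueError("window must be >= 2 and stride >= 1")
    length = len(record)
    if length < window:
        return []
    count = (length - window) // stride + 1
    segments = []
    for i in range(count):
        lo = i * stride
        sl = slice(lo, lo + window)
        segments.append(
            Segment(
                samples=record.ppg[sl],
                fs=record.fs,
                sbp=float(np.mean(record.sbp[sl])),
                dbp=float(np.mean(record.dbp[sl])),
            )
        )
    return segments


def split_segments(
    segments_per_record: list[list[Segment]],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> tuple[list[Segment], list[Segment], list[Segment]]:
    """Chronological per-record train/val/test split.

    Within each record the first ``fractions[0]`` of segments go to training,
    the next ``fractions[1]`` to validation and the remainder to testing
    (floor-based counts, remainder to test), so segments from one record
    never leak across time into an earlier split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if segments_per_record and isinstance(segments_per_record[0], Segment):
        segments_per_record = [segments_per_record]  # single record given flat
    train: list[Segment] = []
    val: list[Segment] = []
    test: list[Segment] = []
    for segs in segments_per_record:
        n = len(segs)
        if n < 2:
            raise ValueError(f"cannot split a record with {n} segment(s)")
        n_train = int(n * fractions[0])
        n_val = int(n * fractions[1])
        train.extend(segs[:n_train])
        val.extend(segs[n_train : n_train + n_val])
        test.extend(segs[n_train + n_val :])
    return train, val, test
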