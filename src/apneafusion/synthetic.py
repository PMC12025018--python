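"""Synthetic paired ECG/SpO2 generator with programmed apnea events.

The ECG is a Gaussian-bump QRS template laid on an RR-spaced impulse train;
the instantaneous RR interval shortens during (and briefly after) each apnea
event.  SpO2 holds a 96-98% baseline and desaturates by at least the
configured depth, lagging each event onset, with a piecewise fall / plateau /
exponential recovery shape.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import Channel, Dialect, SignalRecord

__all__ = ["SimConfig", "simulate_pair", "inject_artifacts", "desat_interval_s"]

#: seconds the elevated heart rate persists past an event's end
TACHY_TAIL_S = 5.0
#: time constant of the SpO2 recovery after the desaturation plateau
RECOVERY_TAU_S = 8.0


@dataclass
class SimConfig:
    """Parameters of the paired simulation.

    ``event_duration_s`` is an inclusive (min, max) range; apnea is by
    definition a cessation of breathing of at least 10 s, so the minimum must
    be >= 10.  ``desat_depth_pct`` must be >= 4 (hypopnea-grade desaturation).
    """

    duration_s: float = 300.0
    fs_ecg: float = 100.0
    fs_spo2: float = 8.0
    apnea_event_rate: float = 30.0  # events per hour
    event_duration_s: tuple[float, float] = (10.0, 25.0)
    desat_depth_pct: float = 5.0
    desat_lag_s: float = 8.0
    rr_baseline_s: float = 0.8
    rr_apnea_modulation: float = 0.25
    artifact_window_fraction: float = 0.0
    noise_floor_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.event_duration_s
        if lo < 10.0:
            raise ValueError(
                f"event_duration_s minimum must be >= 10 s (apnea definition), got {lo}"
            )
        if hi < lo:
            raise ValueError("event_duration_s range must satisfy min <= max")
        if self.desat_depth_pct < 4.0:
            raise ValueError(
                f"desat_depth_pct must be >= 4 (hypopnea-grade), got {self.desat_depth_pct}"
            )
        for name in ("duration_s", "fs_ecg", "fs_spo2", "rr_baseline_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.apnea_event_rate < 0:
            raise ValueError("apnea_event_rate must be >= 0")
        if not 0.0 <= self.artifact_window_fraction <= 1.0:
            raise ValueError("artifact_window_fraction must lie in [0, 1]")
        if not 0.0 <= self.rr_apnea_modulation < 1.0:
            raise ValueError("rr_apnea_modulation must lie in [0, 1)")


def _place_events(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place the target number of non-overlapping events, one per equal slot."""
    n_events = int(round(cfg.apnea_event_rate * cfg.duration_s / 3600.0))
    if n_events == 0:
        return []
    dur_lo, dur_hi = cfg.event_duration_s
    # each slot must fit the longest event plus breathing room on either side
    slot = cfg.duration_s / n_events
    margin = 5.0
    if slot < dur_hi + cfg.desat_lag_s + 2 * margin:
        raise ValueError(
            f"duration {cfg.duration_s} s too short to host {n_events} events of up to "
            f"{dur_hi} s (need >= {n_events * (dur_hi + cfg.desat_lag_s + 2 * margin):.0f} s)"
        )
    events = []
    for i in range(n_events):
        dur = float(rng.uniform(dur_lo, dur_hi))
        lo = i * slot + margin
        hi = (i + 1) * slot - margin - dur - cfg.desat_lag_s
        onset = float(rng.uniform(lo, hi))
        events.append((onset, dur))
    return events


def _qrs_template(fs: float) -> np.ndarray:
    """Gaussian R-bump with small negative side lobes (Q/S)."""
    width = int(round(0.12 * fs))
    t = (np.arange(2 * width + 1) - width) / fs
    r = np.exp(-0.5 * (t / 0.018) ** 2)
    qs = -0.22 * np.exp(-0.5 * ((np.abs(t) - 0.045) / 0.012) ** 2)
    return r + qs


def _rr_at(t: float, events: list[tuple[float, float]], cfg: SimConfig) -> float:
    for onset, dur in events:
        if onset <= t < onset + dur + TACHY_TAIL_S:
            return cfg.rr_baseline_s * (1.0 - cfg.rr_apnea_modulation)
    return cfg.rr_baseline_s


def _synth_ecg(cfg: SimConfig, events: list[tuple[float, float]], rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.duration_s * cfg.fs_ecg))
    x = np.zeros(n)
    template = _qrs_template(cfg.fs_ecg)
    half = len(template) // 2
    t = float(rng.uniform(0.0, cfg.rr_baseline_s))
    while t < cfg.duration_s:
        idx = int(round(t * cfg.fs_ecg))
        lo, hi = idx - half, idx + half + 1
        tlo, thi = max(0, -lo), len(template) - max(0, hi - n)
        if tlo < thi:
            x[max(0, lo):min(n, hi)] += template[tlo:thi]
        rr = _rr_at(t, events, cfg)
        t += rr * (1.0 + 0.02 * float(rng.standard_normal()))
    x += cfg.noise_floor_sd * rng.standard_normal(n)
    return x


def desat_interval_s(event: tuple[float, float], cfg: SimConfig) -> tuple[float, float]:
    """The [start, end) window in which the SpO2 trace is depressed for ``event``."""
    onset, dur = event
    start = onset + cfg.desat_lag_s
    end = onset + dur + cfg.desat_lag_s
    return start, end


def _desat_profile(cfg: SimConfig, events: list[tuple[float, float]], t: np.ndarray) -> np.ndarray:
    """Fractional desaturation in [0, 1] at each time point (1 = full depth)."""
    prof = np.zeros_like(t)
    for event in events:
        start, end = desat_interval_s(event, cfg)
        fall_end = start + (end - start) / 3.0
        d = np.zeros_like(t)
        falling = (t >= start) & (t < fall_end)
        d[falling] = (t[falling] - start) / (fall_end - start)
        d[(t >= fall_end) & (t < end)] = 1.0
        recov = t >= end
        d[recov] = np.exp(-(t[recov] - end) / RECOVERY_TAU_S)
        prof = np.maximum(prof, d)
    return prof


def _synth_spo2(cfg: SimConfig, events: list[tuple[float, float]], rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.duration_s * cfg.fs_spo2))
    t = np.arange(n) / cfg.fs_spo2
    baseline = float(rng.uniform(96.0, 98.0))
    depth = cfg.desat_depth_pct + float(rng.uniform(0.0, 1.0))
    x = baseline - depth * _desat_profile(cfg, events, t)
    x += 0.15 * cfg.noise_floor_sd / 0.03 * rng.standard_normal(n)
    return np.clip(x, 0.0, 100.0)


def simulate_pair(cfg: SimConfig) -> tuple[SignalRecord, SignalRecord]:
    """Generate a paired (ECG, SpO2) recording sharing one apnea event list."""
    rng = np.random.default_rng(cfg.seed)
    events = _place_events(cfg, rng)
    ecg = _synth_ecg(cfg, events, np.random.default_rng(rng.integers(2**63)))
    spo2 = _synth_spo2(cfg, events, np.random.default_rng(rng.integers(2**63)))
    rid = f"sim{cfg.seed:05d}"
    ecg_rec = SignalRecord(ecg, cfg.fs_ecg, Channel.ECG, list(events),
                           Dialect.EVENT_INTERVALS, record_id=rid)
    spo2_rec = SignalRecord(spo2, cfg.fs_spo2, Channel.SPO2, list(events),
                            Dialect.EVENT_INTERVALS, record_id=rid)
    if cfg.artifact_window_fraction > 0:
        ecg_rec, _ = inject_artifacts(ecg_rec, cfg.artifact_window_fraction, seed=cfg.seed + 1)
    return ecg_rec, spo2_rec


def inject_artifacts(
    record: SignalRecord,
    fraction: float,
    seed: int,
    span_s: float = 11.0,
) -> tuple[SignalRecord, list[int]]:
    """Overwrite a fraction of consecutive ``span_s`` blocks with motion-like bursts.

    Returns the corrupted record and the exact list of corrupted span indices
    (ground truth for artifact-rejection tests).  Spans are the non-overlapping
    partition of the record into ``span_s`` blocks; ``round(fraction * n_spans)``
    of them are drawn without replacement.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    n_spans = int(record.duration_s // span_s)
    k = int(round(fraction * n_spans))
    if k == 0:
        return record, []
    rng = np.random.default_rng(seed)
    indices = sorted(int(i) for i in rng.choice(n_spans, size=k, replace=False))
    x = record.samples.copy()
    span_n = int(round(span_s * record.fs))
    amp = 6.0 * max(float(np.std(x)), 1e-3)
    for i in indices:
        lo = i * span_n
        hi = min(lo + span_n, x.size)
        burst = amp * rng.standard_normal(hi - lo)
        # slow baseline excursion on top of the broadband burst
        burst += amp * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * np.arange(hi - lo) / record.fs)
        x[lo:hi] = burst
    if record.channel is Channel.SPO2:
        x = np.clip(x, 0.0, 100.0)
    rec = SignalRecord(x, record.fs, record.channel, list(record.events),
                       record.annotation_dialect, record.record_id)
    return rec, indices
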