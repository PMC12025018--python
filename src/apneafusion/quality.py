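"""Bandpass filtering and autocorrelation-graph artifact rejection.

Each filtered window's autocorrelation function (ACF) is obtained through the
power spectral density (Wiener-Khinchin), lag-0-normalized and truncated.
Windows form the vertices of a complete graph whose edges carry the pairwise
cosine similarity of the ACF vectors; a window's degree weight is the sum of
its similarities to every other window.  Artifact-contaminated windows have
dissimilar ACFs, hence low weights, and the bottom (1 - percentile) fraction
by weight is discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ingest import WindowSet

__all__ = [
    "FilterConfig",
    "AcfQualityReport",
    "bandpass",
    "compute_acf",
    "acf_matrix",
    "similarity_graph",
    "reject_noisy",
    "align_pairs",
]


@dataclass
class FilterConfig:
    """Butterworth bandpass; defaults match a diagnostic-ECG band."""

    low_hz: float = 1.0
    high_hz: float = 40.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be a positive integer")

    def sos(self, fs: float):
        if self.high_hz >= fs / 2.0:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz must be below the Nyquist rate {fs / 2.0} Hz"
            )
        return sps.butter(self.order, (self.low_hz, self.high_hz), btype="bandpass",
                          fs=fs, output="sos")


@dataclass
class AcfQualityReport:
    """Per-window ACF vectors, similarity graph and the keep/discard verdict."""

    acfs: np.ndarray          # (n, L), lag-0-normalized
    similarity: np.ndarray    # (n, n), cosine similarities, unit diagonal
    weights: np.ndarray       # (n,), degree = sum of similarities to others
    keep_mask: np.ndarray     # (n,) bool
    percentile: float

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep_mask)

    @property
    def discarded_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.keep_mask)

    def to_table(self, start_times_s: np.ndarray | None = None) -> str:
        """Delimited-text table: window id, start time, weight, kept flag."""
        lines = ["window\tstart_s\tweight\tkept"]
        for i in range(len(self.weights)):
            t = float(start_times_s[i]) if start_times_s is not None else float("nan")
            lines.append(f"{i}\t{t:.3f}\t{self.weights[i]:.6f}\t{int(self.keep_mask[i])}")
        return "\n".join(lines) + "\n"


def bandpass(wset: WindowSet, cfg: FilterConfig | None = None) -> WindowSet:
    """Filter every window; zero-phase (forward-backward) by default."""
    cfg = cfg or FilterConfig()
    sos = cfg.sos(wset.fs)
    if cfg.zero_phase:
        filtered = sps.sosfiltfilt(sos, wset.windows, axis=-1)
    else:
        filtered = sps.sosfilt(sos, wset.windows, axis=-1)
    return wset.replace(windows=filtered)


def compute_acf(window: np.ndarray, n_lags: int | None = None) -> np.ndarray:
    """Lag-0-normalized linear ACF via the inverse FFT of the power spectrum."""
    return acf_matrix(np.asarray(window, dtype=float)[None, :], n_lags)[0]


def acf_matrix(windows: np.ndarray, n_lags: int | None = None) -> np.ndarray:
    windows = np.asarray(windows, dtype=float)
    n = windows.shape[-1]
    if n_lags is None:
        n_lags = n
    n_lags = min(n_lags, n)
    zero = ~np.any(windows != 0.0, axis=-1)
    if zero.any():
        raise ValueError("ACF of an all-zero window is undefined (zero lag-0 normalizer)")
    nfft = 1 << int(math.ceil(math.log2(2 * n)))  # pad so the circular ACF is linear
    spec = np.fft.rfft(windows, n=nfft, axis=-1)
    acf = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=-1)[..., :n_lags]
    return acf / acf[..., :1]


def similarity_graph(acfs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise cosine similarity of ACF vectors and per-vertex degree weights."""
    acfs = np.asarray(acfs, dtype=float)
    if acfs.ndim != 2 or acfs.shape[0] < 2:
        raise ValueError("need at least two ACF vectors")
    norms = np.linalg.norm(acfs, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm ACF vector has no direction")
    unit = acfs / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    weights = sim.sum(axis=1) - 1.0  # exclude the unit self-similarity
    return sim, weights


def reject_noisy(
    wset: WindowSet,
    percentile: float = 0.95,
    n_lags: int | None = None,
) -> tuple[WindowSet, AcfQualityReport]:
    """Keep the ``ceil(percentile * n)`` windows with the highest degree weights.

    Ties are broken stably by window index.  The ACF lag truncation defaults
    to one second of lags (``round(fs)``).  The graph is built on lags >= 1:
    the lag-0 element is 1 for every window by normalization, and that shared
    constant component would compress all pairwise cosines toward 1,
    drowning out the artifact signature.
    """
    n = len(wset)
    if n < 20:
        raise ValueError(f"need >= 20 windows for a meaningful percentile cut, got {n}")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    if n_lags is None:
        n_lags = max(2, int(round(wset.fs)))
    acfs = acf_matrix(wset.windows, n_lags)
    sim, weights = similarity_graph(acfs[:, 1:])
    n_keep = int(math.ceil(percentile * n))
    order = np.argsort(-weights, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[:n_keep]] = True
    report = AcfQualityReport(acfs, sim, weights, keep, percentile)
    return wset.take(np.flatnonzero(keep)), report


def align_pairs(ecg: WindowSet, spo2: WindowSet) -> tuple[WindowSet, WindowSet]:
    """Restore (ECG, SpO2) window pairing by intersecting (source, start-time) keys."""
    keys_e = ecg.pair_keys()
    keys_s = spo2.pair_keys()
    common = set(keys_e) & set(keys_s)
    idx_e = [i for i, k in enumerate(keys_e) if k in common]
    idx_s = [i for i, k in enumerate(keys_s) if k in common]
    out_e, out_s = ecg.take(idx_e), spo2.take(idx_s)
    if out_e.pair_keys() != out_s.pair_keys():
        raise ValueError("window sets cannot be aligned: key order mismatch")
    if not np.array_equal(out_e.labels, out_s.labels):
        raise ValueError("aligned windows disagree on labels")
    return out_e, out_s
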