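"""Splitting, balancing, training, metrics and the noise-robustness protocol.

Class imbalance is handled by random oversampling of the minority class to
the majority count, followed by a flip (time-reversal) augmentation that
doubles the set.  Robustness is probed by fully corrupting a fixed fraction
of windows with additive white Gaussian noise at a target SNR (default
-20 dB, i.e. noise power 100x signal power) in three scenarios: ECG only,
SpO2 only, or both modalities corrupted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .ingest import WindowSet
from .models import FusionModel
from .nn import Adam, Sequential, softmax_cross_entropy

__all__ = [
    "SplitPlan",
    "NoiseProtocol",
    "NoiseScenario",
    "MetricsReport",
    "TrainConfig",
    "TrainingDiverged",
    "split_indices",
    "balance_and_augment",
    "balance_and_augment_pair",
    "train_branch",
    "train_fusion_head",
    "add_awgn",
    "evaluate",
    "evaluate_fusion",
    "run_noise_protocol",
]


class SplitLevel(str, enum.Enum):
    RECORD = "RECORD"
    SEGMENT = "SEGMENT"


class NoiseScenario(str, enum.Enum):
    ECG_ONLY = "ECG_ONLY"
    SPO2_ONLY = "SPO2_ONLY"
    BOTH = "BOTH"


@dataclass
class SplitPlan:
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    level: SplitLevel = SplitLevel.RECORD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        total = sum(self.ratios)
        self.ratios = tuple(r / total for r in self.ratios)
        self.level = SplitLevel(self.level)


@dataclass
class NoiseProtocol:
    snr_db: float = -20.0
    train_val_fraction: float = 0.20
    test_fraction: float = 0.1142
    scenarios: tuple[NoiseScenario, ...] = (
        NoiseScenario.ECG_ONLY,
        NoiseScenario.SPO2_ONLY,
        NoiseScenario.BOTH,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.train_val_fraction, self.test_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("noise fractions must lie in [0, 1]")
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        self.scenarios = tuple(NoiseScenario(s) for s in self.scenarios)


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "MetricsReport":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.size == 0:
            raise ValueError("cannot score an empty test set")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity, "f1": self.f1,
        }


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 10
    patience: int = 3
    stop_val_acc: float | None = None  # optional early exit once validation is good enough
    restore_best: bool = True  # roll back to the best validation-loss parameters


class TrainingDiverged(RuntimeError):
    pass


def split_indices(wset: WindowSet, plan: SplitPlan) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train/val/test indices, at the record level by default.

    Record-level splitting assigns whole recordings to a partition so that
    overlapping windows never leak across splits.
    """
    rng = np.random.default_rng(plan.seed)
    n = len(wset)
    r_train, r_val, _ = plan.ratios
    if plan.level is SplitLevel.SEGMENT:
        order = rng.permutation(n)
        n_train = int(round(r_train * n))
        n_val = int(round(r_val * n))
        return (np.sort(order[:n_train]), np.sort(order[n_train : n_train + n_val]),
                np.sort(order[n_train + n_val :]))
    sources = sorted(set(wset.source_ids))
    order = [sources[i] for i in rng.permutation(len(sources))]
    k = len(order)
    n_train = max(1, int(round(r_train * k)))
    if k >= 3:
        # keep at least one record each for validation and test
        n_train = min(n_train, k - 2)
        n_val = max(1, min(int(round(r_val * k)), k - n_train - 1))
    else:
        n_train, n_val = min(n_train, max(1, k - 1)), 0
    train_set = set(order[:n_train])
    val_set = set(order[n_train : n_train + n_val])
    groups = ([], [], [])
    for i, sid in enumerate(wset.source_ids):
        groups[0 if sid in train_set else 1 if sid in val_set else 2].append(i)
    return tuple(np.asarray(g, dtype=int) for g in groups)  # type: ignore[return-value]


def _balance_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires both classes present")
    majority = counts.max()
    idx = [np.flatnonzero(labels == c) for c in classes]
    extra = [
        rng.choice(ix, size=majority - len(ix), replace=True) if len(ix) < majority else
        np.zeros(0, dtype=int)
        for ix in idx
    ]
    return np.concatenate([np.arange(len(labels))] + extra)


def balance_and_augment(train: WindowSet, seed: int = 0) -> WindowSet:
    """Oversample the minority class to parity, then add time-reversed copies.

    The output size is ``2 * n_classes * majority_count`` (280 windows for a
    30/70 input, 200 for an already balanced 50/50 one).
    """
    rng = np.random.default_rng(seed)
    idx = _balance_indices(train.labels, rng)
    balanced = train.take(idx)
    flipped = balanced.replace(windows=balanced.windows[:, ::-1].copy())
    return WindowSet(
        np.concatenate([balanced.windows, flipped.windows]),
        np.concatenate([balanced.labels, flipped.labels]),
        train.fs,
        balanced.source_ids + flipped.source_ids,
        np.concatenate([balanced.start_times_s, flipped.start_times_s]),
        train.channel,
    )


def balance_and_augment_pair(
    ecg: WindowSet, spo2: WindowSet, seed: int = 0
) -> tuple[WindowSet, WindowSet]:
    """Apply identical oversampling + flip choices to an aligned modality pair."""
    if not np.array_equal(ecg.labels, spo2.labels):
        raise ValueError("paired window sets disagree on labels")
    rng = np.random.default_rng(seed)
    idx = _balance_indices(ecg.labels, rng)
    out = []
    for wset in (ecg, spo2):
        balanced = wset.take(idx)
        flipped = balanced.replace(windows=balanced.windows[:, ::-1].copy())
        out.append(WindowSet(
            np.concatenate([balanced.windows, flipped.windows]),
            np.concatenate([balanced.labels, flipped.labels]),
            wset.fs,
            balanced.source_ids + flipped.source_ids,
            np.concatenate([balanced.start_times_s, flipped.start_times_s]),
            wset.channel,
        ))
    return out[0], out[1]


def _as_input(wset: WindowSet) -> np.ndarray:
    return wset.windows[:, None, :]


def train_branch(
    model: Sequential,
    train: WindowSet,
    val: WindowSet,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Train a branch with Adam + early stopping; returns the epoch history."""
    cfg = cfg or TrainConfig()
    x_train, y_train = _as_input(train), train.labels.astype(int)
    x_val, y_val = _as_input(val), val.labels.astype(int)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    best_val = math.inf
    best_state = None
    stall = 0
    n_softmax = len(model.layers) - 1  # logits live just below the softmax layer
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            logits = model.forward(x_train[sel], training=True, upto=n_softmax)
            loss, dlogits = softmax_cross_entropy(logits, y_train[sel])
            if not math.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss {loss} at epoch {epoch}")
            model.backward(dlogits, start=n_softmax - 1)
            opt.step()
            losses.append(loss)
        val_logits = model.forward(x_val, upto=n_softmax)
        val_loss, _ = softmax_cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
        if val_loss < best_val - 1e-6:
            best_val, stall = val_loss, 0
            best_state = model.state_dict()
        else:
            stall += 1
            if stall >= cfg.patience:
                break
        if cfg.stop_val_acc is not None and val_acc >= cfg.stop_val_acc:
            break
    if cfg.restore_best and best_state is not None:
        model.load_state_dict(best_state)
    return history


def train_fusion_head(
    fusion: FusionModel,
    train_pair: tuple[WindowSet, WindowSet],
    val_pair: tuple[WindowSet, WindowSet],
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Train only the fusion head; the frozen trunks are run once as feature extractors.

    Selective dropout is re-drawn on the cached flatten features every batch,
    exactly as it would be inside a full forward pass (the trunks are frozen,
    so their features are constant across epochs).
    """
    cfg = cfg or TrainConfig()
    feats_train = fusion.features([_as_input(w) for w in train_pair])
    feats_val = fusion.features([_as_input(w) for w in val_pair])
    y_train = train_pair[0].labels.astype(int)
    y_val = val_pair[0].labels.astype(int)
    z_val = np.concatenate(feats_val, axis=1)
    head = fusion.head
    opt = Adam(head.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    best_val = math.inf
    best_state = None
    stall = 0
    n_softmax = len(head.layers) - 1
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            dropped = [
                d.forward(f[sel], training=True)
                for d, f in zip(fusion.dropouts, feats_train)
            ]
            logits = head.forward(np.concatenate(dropped, axis=1), training=True, upto=n_softmax)
            loss, dlogits = softmax_cross_entropy(logits, y_train[sel])
            if not math.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss {loss} at epoch {epoch}")
            head.backward(dlogits, start=n_softmax - 1)
            opt.step()
            losses.append(loss)
        val_logits = head.forward(z_val, upto=n_softmax)
        val_loss, _ = softmax_cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
        if val_loss < best_val - 1e-6:
            best_val, stall = val_loss, 0
            best_state = head.state_dict()
        else:
            stall += 1
            if stall >= cfg.patience:
                break
        if cfg.stop_val_acc is not None and val_acc >= cfg.stop_val_acc:
            break
    if cfg.restore_best and best_state is not None:
        head.load_state_dict(best_state)
    return history


def add_awgn(
    wset: WindowSet,
    snr_db: float,
    fraction: float,
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> tuple[WindowSet, np.ndarray]:
    """Fully corrupt ``round(fraction * n)`` windows with AWGN at ``snr_db``.

    Noise power is set per window from that window's own mean-square power:
    P_noise = P_signal / 10^(snr_db / 10).  Returns the corrupted set and the
    sorted corrupted-window indices.  ``indices`` forces the corrupted set
    (used when both modalities must corrupt the same windows).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = len(wset)
    rng = np.random.default_rng(seed)
    if indices is not None:
        indices = np.sort(np.asarray(indices, dtype=int))
        k = indices.size
    else:
        k = int(round(fraction * n))
        if k:
            indices = np.sort(rng.choice(n, size=k, replace=False))
    if k == 0:
        return wset, np.zeros(0, dtype=int)
    windows = wset.windows.copy()
    p_signal = (windows[indices] ** 2).mean(axis=1)
    if np.any(p_signal == 0.0):
        raise ValueError("cannot set an SNR against a zero-power window")
    sd = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    noise = rng.standard_normal((k, wset.window_samples))
    # rescale each draw to the exact target RMS so the per-window SNR is met
    noise *= sd[:, None] / np.sqrt((noise**2).mean(axis=1, keepdims=True))
    windows[indices] += noise
    return wset.replace(windows=windows), indices


def evaluate(model: Sequential, test: WindowSet) -> MetricsReport:
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty window set")
    preds = model.predict(_as_input(test))
    return MetricsReport.from_predictions(test.labels, preds)


def evaluate_fusion(fusion: FusionModel, pair: tuple[WindowSet, WindowSet]) -> MetricsReport:
    ecg, spo2 = pair
    if len(ecg) != len(spo2) or not np.array_equal(ecg.labels, spo2.labels):
        raise ValueError("misaligned ECG/SpO2 test pair")
    if len(ecg) == 0:
        raise ValueError("cannot evaluate on an empty pair")
    preds = fusion.predict([_as_input(ecg), _as_input(spo2)])
    return MetricsReport.from_predictions(ecg.labels, preds)


def run_noise_protocol(
    branch_models: dict[str, Sequential],
    fusion_model: FusionModel,
    test_pair: tuple[WindowSet, WindowSet],
    protocol: NoiseProtocol | None = None,
) -> dict[str, dict[str, MetricsReport]]:
    """Evaluate each branch and the fused model under the three noise scenarios.

    Per scenario, ``test_fraction`` of the windows in the designated modality
    (or both, with identical window indices) are fully corrupted at
    ``snr_db``; each scenario uses its own seeded draw.
    """
    protocol = protocol or NoiseProtocol()
    ecg, spo2 = test_pair
    if len(ecg) != len(spo2) or not np.array_equal(ecg.labels, spo2.labels):
        raise ValueError("misaligned ECG/SpO2 test pair")
    results: dict[str, dict[str, MetricsReport]] = {}
    for offset, scenario in enumerate(protocol.scenarios):
        seed = protocol.seed + 1000 * (offset + 1)
        ecg_s, spo2_s = ecg, spo2
        if scenario is NoiseScenario.ECG_ONLY:
            ecg_s, _ = add_awgn(ecg, protocol.snr_db, protocol.test_fraction, seed=seed)
        elif scenario is NoiseScenario.SPO2_ONLY:
            spo2_s, _ = add_awgn(spo2, protocol.snr_db, protocol.test_fraction, seed=seed)
        elif scenario is NoiseScenario.BOTH:
            # the same windows are corrupted in both modalities, with
            # independently drawn noise
            ecg_s, idx = add_awgn(ecg, protocol.snr_db, protocol.test_fraction, seed=seed)
            spo2_s, _ = add_awgn(spo2, protocol.snr_db, protocol.test_fraction,
                                 seed=seed + 17, indices=idx)
        results[scenario.value] = {
            "ecg": evaluate(branch_models["ecg"], ecg_s),
            "spo2": evaluate(branch_models["spo2"], spo2_s),
            "fusion": evaluate_fusion(fusion_model, (ecg_s, spo2_s)),
        }
    return results
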