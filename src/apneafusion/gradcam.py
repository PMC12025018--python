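"""1-D Grad-CAM heatmaps, importance banding and localization scoring.

For a chosen conv feature map A^k (k channels x W temporal positions), the
channel weight is the temporal mean of the class-score gradient,
a_c^k = (1/Z) sum_i dy^c/dA_i^k with Z = W, and the raw map is
ReLU(sum_k a_c^k A^k).  The map is linearly upsampled to the input length,
min-max normalized to [0, 1] and quantized into LOW / MODERATE / HIGH bands
(blue / red / green) at configurable thresholds.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .models import FusionModel
from .nn import Conv1d, ReLU, Sequential

__all__ = [
    "Band",
    "BandConfig",
    "GradCamResult",
    "gradcam",
    "gradcam_fusion",
    "quantize_bands",
    "localization_score",
    "plot_banded_window",
]


class Band(enum.IntEnum):
    LOW = 0
    MODERATE = 1
    HIGH = 2


#: plotting colors: blue = lowest, red = moderate, green = highest importance
BAND_COLORS = {Band.LOW: "tab:blue", Band.MODERATE: "tab:red", Band.HIGH: "tab:green"}


@dataclass
class BandConfig:
    thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        t_low, t_high = self.thresholds
        if not 0.0 < t_low < t_high < 1.0:
            raise ValueError("need 0 < t_low < t_high < 1")


@dataclass
class GradCamResult:
    feature_maps: np.ndarray      # (k, W)
    channel_weights: np.ndarray   # (k,)
    raw_map: np.ndarray           # (W,), nonnegative
    upsampled_map: np.ndarray     # (input_len,), in [0, 1]
    target_class: int
    Z: int
    bands: np.ndarray | None = None

    @property
    def width(self) -> int:
        return self.raw_map.size


def _target_layer_index(model: Sequential, target_layer: int | None) -> int:
    """Index of the feature-map layer: the ReLU after the last conv by default."""
    if target_layer is not None:
        idx = target_layer
    else:
        conv_idx = [i for i, l in enumerate(model.layers) if isinstance(l, Conv1d)]
        if not conv_idx:
            raise ValueError("model has no convolutional layer to explain")
        idx = conv_idx[-1]
        if idx + 1 < len(model.layers) and isinstance(model.layers[idx + 1], ReLU):
            idx += 1
    return idx


def _assemble(feature_map: np.ndarray, grad: np.ndarray, input_len: int,
              target_class: int) -> GradCamResult:
    k, w = feature_map.shape
    weights = grad.mean(axis=1)  # (1/Z) sum over temporal positions, Z = W
    raw = np.maximum((weights[:, None] * feature_map).sum(axis=0), 0.0)
    positions = np.linspace(0.0, 1.0, w) if w > 1 else np.array([0.5])
    target = np.linspace(0.0, 1.0, input_len)
    up = np.interp(target, positions, raw)
    lo, hi = float(up.min()), float(up.max())
    norm = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return GradCamResult(feature_map, weights, raw, norm, target_class, Z=w)


def gradcam(
    model: Sequential,
    window: np.ndarray,
    target_class: int = 1,
    target_layer: int | None = None,
) -> GradCamResult:
    """Grad-CAM of a single-branch model for one window.

    The class score y^c is the pre-softmax logit of ``target_class``; the
    feature map defaults to the (post-ReLU) output of the last conv layer.
    """
    window = np.asarray(window, dtype=float).ravel()
    idx = _target_layer_index(model, target_layer)
    x = window[None, None, :]
    acts = model.forward_collect(x)
    if acts[idx].ndim != 3:
        raise ValueError(f"target layer {idx} has no temporal extent")
    logits = acts[-2]  # layer below the softmax
    seed_grad = np.zeros_like(logits)
    seed_grad[0, target_class] = 1.0
    grad = model.backward(seed_grad, start=len(model.layers) - 2, stop=idx)
    return _assemble(acts[idx][0], grad[0], window.size, target_class)


def gradcam_fusion(
    fusion: FusionModel,
    windows: list[np.ndarray],
    target_class: int = 1,
) -> list[GradCamResult]:
    """Per-branch Grad-CAM maps of the fused class score (one per modality)."""
    inputs = [np.asarray(w, dtype=float).ravel()[None, None, :] for w in windows]
    acts_per_trunk = [t.forward_collect(x) for t, x in zip(fusion.trunks, inputs)]
    feats = [acts[-1] for acts in acts_per_trunk]
    z = np.concatenate(feats, axis=1)
    head = fusion.head
    head_acts = head.forward_collect(z)
    seed_grad = np.zeros_like(head_acts[-2])
    seed_grad[0, target_class] = 1.0
    gz = head.backward(seed_grad, start=len(head.layers) - 2)
    results = []
    offset = 0
    for trunk, acts, x in zip(fusion.trunks, acts_per_trunk, inputs):
        width = acts[-1].shape[1]
        g_feat = gz[:, offset : offset + width]
        offset += width
        idx = _target_layer_index(trunk, None)
        grad = trunk.backward(g_feat, start=len(trunk.layers) - 1, stop=idx)
        results.append(_assemble(acts[idx][0], grad[0], x.shape[2], target_class))
    return results


def quantize_bands(result: GradCamResult, cfg: BandConfig | None = None) -> GradCamResult:
    """Assign per-sample bands: [0, t_low) LOW, [t_low, t_high) MODERATE, [t_high, 1] HIGH."""
    cfg = cfg or BandConfig()
    t_low, t_high = cfg.thresholds
    v = result.upsampled_map
    bands = np.where(v < t_low, Band.LOW, np.where(v < t_high, Band.MODERATE, Band.HIGH))
    if v.size and v.max() == v.min():
        warnings.warn("degenerate (constant) importance map: all samples in one band",
                      stacklevel=2)
    result.bands = bands.astype(np.int8)
    return result


def localization_score(
    result: GradCamResult,
    event_region: tuple[int, int],
    eps: float = 1e-9,
) -> float:
    """Mean importance inside a [start, stop) sample interval over mean outside."""
    a, b = int(event_region[0]), int(event_region[1])
    v = result.upsampled_map
    if not 0 <= a < b <= v.size:
        raise ValueError(f"event region [{a}, {b}) outside the window of {v.size} samples")
    inside = v[a:b]
    outside = np.concatenate([v[:a], v[b:]])
    if inside.size == 0 or outside.size == 0:
        raise ValueError("event region leaves an empty inside or outside segment")
    return float(inside.mean() / max(float(outside.mean()), eps))


def plot_banded_window(
    window: np.ndarray,
    result: GradCamResult,
    path: str,
    fs: float = 1.0,
    title: str = "",
) -> None:
    """Trace colored by importance band, with the color-bar legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.bands is None:
        raise ValueError("quantize_bands() must run before plotting")
    window = np.asarray(window, dtype=float).ravel()
    t = np.arange(window.size) / fs
    fig, ax = plt.subplots(figsize=(9, 3))
    for band in Band:
        mask = result.bands == band
        y = np.where(mask, window, np.nan)
        ax.plot(t, y, color=BAND_COLORS[band], lw=1.0,
                label=f"{band.name.lower()} importance")
    ax.set_xlabel("time (s)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
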