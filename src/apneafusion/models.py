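"""Branch CNN architectures, selective-dropout plans and the fused model.

The two single-signal branches are fixed: three convolution layers (the ECG
branch opens with 3 kernels of size 100 at stride 2, then 50x10 and 30x30;
the SpO2 branch uses 6x25, 50x10 and 30x15), each followed by a 2/2 max pool,
then flatten, dropout 0.25 and a 2-unit softmax head, with batch norm on the
raw input and ReLU activations elsewhere.  Fusion removes both output heads,
concatenates the flatten features (applying selective dropout to the
higher-rate branch during training only) and attaches a fresh dense head; all
pre-concatenation parameters stay frozen.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    ReLU,
    Sequential,
    Softmax,
    conv_output_length,
    pool_output_length,
)
from .records import Channel

__all__ = [
    "BranchSpec",
    "DropoutMode",
    "DropoutPlan",
    "FusionPlan",
    "FusionModel",
    "ecg_branch_spec",
    "spo2_branch_spec",
    "propagate_shapes",
    "flatten_width",
    "build_branch",
    "selective_dropout_rates",
    "build_fusion",
]

ECG_CONV_LAYERS: tuple[tuple[int, int, int], ...] = ((3, 100, 2), (50, 10, 1), (30, 30, 1))
SPO2_CONV_LAYERS: tuple[tuple[int, int, int], ...] = ((6, 25, 1), (50, 10, 1), (30, 15, 1))


@dataclass
class BranchSpec:
    """One branch's architecture: (n_kernels, kernel_size, stride) triples."""

    channel: Channel
    input_len: int
    conv_layers: tuple[tuple[int, int, int], ...]
    pool_size: int = 2
    dropout_rate: float = 0.25
    padding: str = "same"
    input_batchnorm: bool = True
    n_classes: int = 2

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        if self.input_len < 1:
            raise ValueError("input_len must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def ecg_branch_spec(input_len: int = 1100, padding: str = "same") -> BranchSpec:
    return BranchSpec(Channel.ECG, input_len, ECG_CONV_LAYERS, padding=padding)


def spo2_branch_spec(input_len: int = 88, padding: str = "same") -> BranchSpec:
    return BranchSpec(Channel.SPO2, input_len, SPO2_CONV_LAYERS, padding=padding)


def propagate_shapes(spec: BranchSpec) -> list[tuple[int, int]]:
    """(channels, length) after each conv+pool block; raises at the failing layer."""
    length = spec.input_len
    shapes: list[tuple[int, int]] = []
    for i, (n_kernels, kernel, stride) in enumerate(spec.conv_layers, start=1):
        try:
            length = conv_output_length(length, kernel, stride, spec.padding)
        except ValueError as exc:
            raise ValueError(f"conv{i} ({n_kernels}x{kernel}, stride {stride}): {exc}") from exc
        if length < spec.pool_size:
            raise ValueError(
                f"pool after conv{i}: length {length} shorter than pool size {spec.pool_size}"
            )
        length = pool_output_length(length, spec.pool_size, spec.pool_size)
        shapes.append((n_kernels, length))
    return shapes


def flatten_width(spec: BranchSpec) -> int:
    channels, length = propagate_shapes(spec)[-1]
    return channels * length


def build_branch(spec: BranchSpec, seed: int = 0) -> Sequential:
    """Instantiate a branch: [BN] -> (conv -> ReLU -> pool) x3 -> flatten -> dropout -> dense -> softmax."""
    propagate_shapes(spec)  # raise early, naming the failing layer
    rng = np.random.default_rng(seed)
    layers: list = []
    if spec.input_batchnorm:
        layers.append(BatchNorm1d(1))
    in_ch = 1
    for n_kernels, kernel, stride in spec.conv_layers:
        layers.append(Conv1d(in_ch, n_kernels, kernel, stride, spec.padding, rng=rng))
        layers.append(ReLU())
        layers.append(MaxPool1d(spec.pool_size))
        in_ch = n_kernels
    layers.append(Flatten())
    layers.append(Dropout(spec.dropout_rate, rng=np.random.default_rng(seed + 1)))
    layers.append(Dense(flatten_width(spec), spec.n_classes, rng=rng))
    layers.append(Softmax())
    model = Sequential(layers)
    model.spec = spec  # type: ignore[attr-defined]
    return model


def flatten_layer_index(model: Sequential) -> int:
    for i, layer in enumerate(model.layers):
        if isinstance(layer, Flatten):
            return i
    raise ValueError("model has no Flatten layer")


class DropoutMode(str, enum.Enum):
    MATCHED_FS = "MATCHED_FS"
    MISMATCHED_NEURONS = "MISMATCHED_NEURONS"


@dataclass
class DropoutPlan:
    """Per-branch selective-dropout ratios for the fusion flatten features."""

    rates: tuple[float, ...]
    fs: tuple[float, ...]
    neurons: tuple[int, ...]
    mode: DropoutMode

    def __post_init__(self) -> None:
        self.mode = DropoutMode(self.mode)
        if any(not 0.0 <= r < 1.0 for r in self.rates):
            raise ValueError("all dropout rates must lie in [0, 1)")


def selective_dropout_rates(
    fs: Sequence[float],
    neurons: Sequence[int],
    mode: DropoutMode = DropoutMode.MATCHED_FS,
) -> DropoutPlan:
    """Dropout ratio per branch.

    MATCHED_FS: rate_j = 1 - min(fs) / fs_j — zero for the slowest sensor.
    MISMATCHED_NEURONS: rate_j = 1 - min(neurons) / neurons_j — zero for the
    narrowest flatten layer.
    """
    mode = DropoutMode(mode)
    if len(fs) != len(neurons):
        raise ValueError("fs and neurons lists must have equal length")
    if any(f <= 0 for f in fs) or any(n <= 0 for n in neurons):
        raise ValueError("sampling rates and neuron counts must be positive")
    if len(fs) == 1:
        warnings.warn("single-branch dropout plan is a no-op", stacklevel=2)
        return DropoutPlan((0.0,), tuple(fs), tuple(neurons), mode)
    if mode is DropoutMode.MATCHED_FS:
        low = min(fs)
        rates = tuple(1.0 - low / f for f in fs)
    else:
        low = min(neurons)
        rates = tuple(1.0 - low / n for n in neurons)
    return DropoutPlan(rates, tuple(fs), tuple(neurons), mode)


@dataclass
class FusionPlan:
    """How the fused model is assembled from trained branches."""

    flatten_widths: tuple[int, ...]
    selective_dropout: DropoutPlan
    head_hidden: tuple[int, ...] = (64,)
    n_classes: int = 2

    @property
    def concat_width(self) -> int:
        return sum(self.flatten_widths)


class FusionModel:
    """Frozen branch trunks + selective dropout + a trainable dense head.

    The trunks are the branch layer stacks up to and including their flatten
    layers; their parameters are never updated here.  Selective dropout is
    applied to each branch's flatten features during training only.
    """

    def __init__(self, trunks: list[Sequential], plan: FusionPlan, seed: int = 0) -> None:
        if len(trunks) != len(plan.flatten_widths):
            raise ValueError("one flatten width per trunk required")
        self.trunks = trunks
        self.plan = plan
        rates = plan.selective_dropout.rates
        if len(rates) != len(trunks):
            raise ValueError(
                f"dropout plan covers {len(rates)} branches but {len(trunks)} trunks given"
            )
        self.dropouts = [
            Dropout(r, rng=np.random.default_rng(seed + 100 + i)) for i, r in enumerate(rates)
        ]
        rng = np.random.default_rng(seed)
        layers: list = []
        n_in = plan.concat_width
        for width in plan.head_hidden:
            layers.append(Dense(n_in, width, rng=rng))
            layers.append(ReLU())
            n_in = width
        layers.append(Dense(n_in, plan.n_classes, rng=rng))
        layers.append(Softmax())
        self.head = Sequential(layers)

    # -- forward -----------------------------------------------------------
    def features(self, inputs: Sequence[np.ndarray], batch: int = 256) -> list[np.ndarray]:
        """Per-branch flatten features (trunks always run in inference mode)."""
        out = []
        for trunk, x in zip(self.trunks, inputs):
            chunks = [trunk.forward(x[i : i + batch]) for i in range(0, x.shape[0], batch)]
            out.append(np.concatenate(chunks))
        return out

    def forward(self, inputs: Sequence[np.ndarray], training: bool = False) -> np.ndarray:
        feats = self.features(inputs)
        if training:
            feats = [d.forward(f, training=True) for d, f in zip(self.dropouts, feats)]
        return self.head.forward(np.concatenate(feats, axis=1), training=training)

    def predict(self, inputs: Sequence[np.ndarray], batch: int = 256) -> np.ndarray:
        n = inputs[0].shape[0]
        out = []
        for i in range(0, n, batch):
            out.append(self.forward([x[i : i + batch] for x in inputs]).argmax(axis=-1))
        return np.concatenate(out) if out else np.zeros(0, dtype=int)

    # -- persistence -------------------------------------------------------
    def checksum_branches(self) -> float:
        return float(sum(t.checksum() for t in self.trunks))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, trunk in enumerate(self.trunks):
            for key, arr in trunk.state_dict().items():
                state[f"trunk{i}.{key}"] = arr
        for key, arr in self.head.state_dict().items():
            state[f"head.{key}"] = arr
        return state

    def manifest(self) -> dict:
        return {
            "flatten_widths": list(self.plan.flatten_widths),
            "head_hidden": list(self.plan.head_hidden),
            "dropout": {
                "rates": list(self.plan.selective_dropout.rates),
                "fs": list(self.plan.selective_dropout.fs),
                "neurons": list(self.plan.selective_dropout.neurons),
                "mode": self.plan.selective_dropout.mode.value,
            },
        }


def flatten_layer_index_of_trunk(trunk: Sequential) -> int:
    return flatten_layer_index(trunk)


def branch_trunk(model: Sequential) -> Sequential:
    """The branch cut after its flatten layer (head and dropout removed)."""
    idx = flatten_layer_index(model)
    return Sequential(model.layers[: idx + 1])


def build_fusion(
    branch_ecg: Sequential,
    branch_spo2: Sequential,
    plan: FusionPlan | None = None,
    mode: DropoutMode = DropoutMode.MATCHED_FS,
    fs: Sequence[float] = (100.0, 8.0),
    head_hidden: Sequence[int] = (64,),
    seed: int = 0,
) -> FusionModel:
    """Assemble the fused model from two trained branches.

    Output heads are removed, the flatten features concatenated, and a fresh
    dense head attached.  When no explicit plan is given, a selective-dropout
    plan is derived from ``mode`` using the branch sampling rates and flatten
    widths.
    """
    trunks = [branch_trunk(branch_ecg), branch_trunk(branch_spo2)]
    widths = tuple(flatten_width(b.spec) for b in (branch_ecg, branch_spo2))
    if plan is None:
        dplan = selective_dropout_rates(tuple(fs), widths, mode)
        plan = FusionPlan(widths, dplan, tuple(head_hidden))
    if tuple(plan.flatten_widths) != widths:
        raise ValueError(
            f"plan flatten widths {plan.flatten_widths} inconsistent with branches {widths}"
        )
    return FusionModel(trunks, plan, seed=seed)


# -- checkpointing ---------------------------------------------------------

def save_branch(model: Sequential, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    spec = model.spec
    manifest = {
        "channel": spec.channel.value,
        "input_len": spec.input_len,
        "conv_layers": [list(c) for c in spec.conv_layers],
        "padding": spec.padding,
        "dropout_rate": spec.dropout_rate,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_branch(path: str | Path) -> Sequential:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = BranchSpec(
        Channel(manifest["channel"]),
        manifest["input_len"],
        tuple(tuple(c) for c in manifest["conv_layers"]),
        padding=manifest["padding"],
        dropout_rate=manifest["dropout_rate"],
    )
    model = build_branch(spec)
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
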