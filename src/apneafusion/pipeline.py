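"""Stage-wise reproducible pipeline: simulate -> ingest -> preprocess ->
train -> fuse -> evaluate -> explain.

Each stage writes its artifacts under ``out_dir/<stage>/`` together with the
run's config hash and seed, and checks that its upstream stage has run.
Identical config + seed yields bit-identical metric reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig, config_hash, save_config
from .gradcam import gradcam, quantize_bands
from .ingest import WindowSet, segment_record
from .models import (
    build_branch,
    build_fusion,
    ecg_branch_spec,
    load_branch,
    save_branch,
    spo2_branch_spec,
)
from .quality import align_pairs, bandpass, reject_noisy
from .records import write_record
from .synthetic import simulate_pair
from .training import (
    balance_and_augment_pair,
    evaluate,
    evaluate_fusion,
    run_noise_protocol,
    split_indices,
    train_branch,
    train_fusion_head,
)

__all__ = ["STAGES", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "ingest", "preprocess", "train", "fuse", "evaluate", "explain")
_REQUIRES = {
    "ingest": "simulate",
    "preprocess": "ingest",
    "train": "preprocess",
    "fuse": "train",
    "evaluate": "fuse",
    "explain": "fuse",
}

log = logging.getLogger("apneafusion")


class PipelineError(RuntimeError):
    pass


def _require(out_dir: Path, stage: str) -> None:
    needed = _REQUIRES.get(stage)
    if needed and not (out_dir / needed / ".done").exists():
        raise PipelineError(
            f"stage '{stage}' requires artifacts from stage '{needed}'; run it first"
        )


def _mark_done(out_dir: Path, stage: str, cfg: RunConfig) -> None:
    d = out_dir / stage
    d.mkdir(parents=True, exist_ok=True)
    (d / ".done").write_text(json.dumps({"config": config_hash(cfg), "seed": cfg.seed}))


def _save_windowset(wset: WindowSet, path: Path) -> None:
    np.savez(path, windows=wset.windows, labels=wset.labels, fs=wset.fs,
             start_times_s=wset.start_times_s,
             source_ids=np.asarray(wset.source_ids),
             channel=str(wset.channel.value if wset.channel else ""))


def _load_windowset(path: Path) -> WindowSet:
    with np.load(path, allow_pickle=False) as d:
        channel = str(d["channel"]) or None
        return WindowSet(d["windows"], d["labels"], float(d["fs"]),
                         [str(s) for s in d["source_ids"]], d["start_times_s"], channel)


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    for r in range(cfg.n_records):
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed * 1009 + r)
        ecg, spo2 = simulate_pair(sim)
        write_record(ecg, d / f"{ecg.record_id}_ecg.txt")
        write_record(spo2, d / f"{spo2.record_id}_spo2.txt")
    log.info("simulate: wrote %d record pairs", cfg.n_records)


def _stage_ingest(cfg: RunConfig, out: Path) -> None:
    from .records import read_text_record

    d = out / "ingest"
    d.mkdir(parents=True, exist_ok=True)
    ecg_sets, spo2_sets = [], []
    for path in sorted((out / "simulate").glob("*_ecg.txt")):
        ecg_sets.append(segment_record(read_text_record(path), cfg.segmentation))
        spo2_path = path.with_name(path.name.replace("_ecg", "_spo2"))
        spo2_sets.append(segment_record(read_text_record(spo2_path), cfg.segmentation))
    if not ecg_sets:
        raise PipelineError("no simulated records found to ingest")
    from .experiments import _concat

    _save_windowset(_concat(ecg_sets), d / "ecg.npz")
    _save_windowset(_concat(spo2_sets), d / "spo2.npz")


def _stage_preprocess(cfg: RunConfig, out: Path) -> None:
    d = out / "preprocess"
    d.mkdir(parents=True, exist_ok=True)
    ecg = _load_windowset(out / "ingest" / "ecg.npz")
    spo2 = _load_windowset(out / "ingest" / "spo2.npz")
    ecg = bandpass(ecg, cfg.bandpass)
    # the ACF graph is built per recording; SpO2 passes through untouched
    kept_sets = []
    tables = []
    for sid in sorted(set(ecg.source_ids)):
        idx = [i for i, s in enumerate(ecg.source_ids) if s == sid]
        sub = ecg.take(idx)
        if len(sub) < 20:
            kept_sets.append(sub)
            continue
        kept, report = reject_noisy(sub, cfg.quality_percentile)
        kept_sets.append(kept)
        tables.append(f"# record {sid}\n" + report.to_table(sub.start_times_s))
    from .experiments import _concat

    ecg_kept = _concat(kept_sets)
    ecg_kept, spo2_kept = align_pairs(ecg_kept, spo2)
    (d / "quality_report.tsv").write_text("\n".join(tables) + "\n" if tables else "")
    _save_windowset(ecg_kept, d / "ecg.npz")
    _save_windowset(spo2_kept, d / "spo2.npz")


def _split_sets(cfg: RunConfig, out: Path):
    ecg = _load_windowset(out / "preprocess" / "ecg.npz")
    spo2 = _load_windowset(out / "preprocess" / "spo2.npz")
    tr, va, te = split_indices(ecg, dataclasses.replace(cfg.split, seed=cfg.seed))
    return tuple((ecg.take(i), spo2.take(i)) for i in (tr, va, te))


def _stage_train(cfg: RunConfig, out: Path) -> None:
    d = out / "train"
    d.mkdir(parents=True, exist_ok=True)
    (train_pair, val_pair, _) = _split_sets(cfg, out)
    train_pair = balance_and_augment_pair(*train_pair, seed=cfg.seed)
    models = {}
    for name, spec_fn, idx in (("ecg", ecg_branch_spec, 0), ("spo2", spo2_branch_spec, 1)):
        model = build_branch(spec_fn(train_pair[idx].window_samples), seed=cfg.seed + idx)
        hist = train_branch(model, train_pair[idx], val_pair[idx], cfg.train, seed=cfg.seed + idx)
        save_branch(model, d / f"{name}_branch.npz")
        lines = ["epoch,train_loss,val_loss,val_acc"] + [
            f"{h['epoch']},{h['train_loss']:.6f},{h['val_loss']:.6f},{h['val_acc']:.6f}"
            for h in hist
        ]
        (d / f"{name}_history.csv").write_text("\n".join(lines) + "\n")
        models[name] = model


def _stage_fuse(cfg: RunConfig, out: Path) -> None:
    d = out / "fuse"
    d.mkdir(parents=True, exist_ok=True)
    ecg_model = load_branch(out / "train" / "ecg_branch.npz")
    spo2_model = load_branch(out / "train" / "spo2_branch.npz")
    (train_pair, val_pair, _) = _split_sets(cfg, out)
    train_pair = balance_and_augment_pair(*train_pair, seed=cfg.seed)
    fusion = build_fusion(
        ecg_model, spo2_model, mode=cfg.dropout_mode,
        fs=(train_pair[0].fs, train_pair[1].fs),
        head_hidden=cfg.head_hidden, seed=cfg.seed,
    )
    train_fusion_head(fusion, train_pair, val_pair, cfg.train, seed=cfg.seed)
    np.savez(d / "fusion.npz", **fusion.state_dict())
    (d / "fusion.json").write_text(json.dumps(fusion.manifest(), indent=2, sort_keys=True))


def _rebuild_fusion(cfg: RunConfig, out: Path):
    ecg_model = load_branch(out / "train" / "ecg_branch.npz")
    spo2_model = load_branch(out / "train" / "spo2_branch.npz")
    manifest = json.loads((out / "fuse" / "fusion.json").read_text())
    fusion = build_fusion(
        ecg_model, spo2_model, mode=manifest["dropout"]["mode"],
        fs=tuple(manifest["dropout"]["fs"]),
        head_hidden=tuple(manifest["head_hidden"]), seed=cfg.seed,
    )
    with np.load(out / "fuse" / "fusion.npz") as data:
        state = {k: data[k] for k in data.files}
    head_state = {k[len("head."):]: v for k, v in state.items() if k.startswith("head.")}
    fusion.head.load_state_dict(head_state)
    return ecg_model, spo2_model, fusion


def _stage_evaluate(cfg: RunConfig, out: Path) -> None:
    d = out / "evaluate"
    d.mkdir(parents=True, exist_ok=True)
    ecg_model, spo2_model, fusion = _rebuild_fusion(cfg, out)
    (_, _, test_pair) = _split_sets(cfg, out)
    report = {
        "config": config_hash(cfg),
        "seed": cfg.seed,
        "clean": {
            "ecg": evaluate(ecg_model, test_pair[0]).to_dict(),
            "spo2": evaluate(spo2_model, test_pair[1]).to_dict(),
            "fusion": evaluate_fusion(fusion, test_pair).to_dict(),
        },
    }
    noisy = run_noise_protocol(
        {"ecg": ecg_model, "spo2": spo2_model}, fusion, test_pair,
        dataclasses.replace(cfg.noise, seed=cfg.seed),
    )
    report["noisy"] = {
        scen: {name: rep.to_dict() for name, rep in reps.items()}
        for scen, reps in noisy.items()
    }
    (d / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def _stage_explain(cfg: RunConfig, out: Path, n_windows: int = 4, png: bool = False) -> None:
    d = out / "explain"
    d.mkdir(parents=True, exist_ok=True)
    ecg_model, spo2_model, fusion = _rebuild_fusion(cfg, out)
    (_, _, (ecg_te, spo2_te)) = _split_sets(cfg, out)
    apneic = np.flatnonzero(spo2_te.labels == 1)[:n_windows]
    lines = ["window,channel,sample,band,importance"]
    for i in apneic:
        for name, model, wset in (("ecg", ecg_model, ecg_te), ("spo2", spo2_model, spo2_te)):
            res = quantize_bands(gradcam(model, wset.windows[i], target_class=1), cfg.bands)
            for s in range(res.bands.size):
                lines.append(f"{i},{name},{s},{int(res.bands[s])},{res.upsampled_map[s]:.6f}")
            if png:
                from .gradcam import plot_banded_window

                plot_banded_window(wset.windows[i], res, str(d / f"win{i}_{name}.png"),
                                   fs=wset.fs, title=f"window {i} ({name})")
    (d / "bands.csv").write_text("\n".join(lines) + "\n")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "ingest": _stage_ingest,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "fuse": _stage_fuse,
    "evaluate": _stage_evaluate,
    "explain": _stage_explain,
}


def run_pipeline(cfg: RunConfig, out_dir: str | Path, stages: tuple[str, ...] | None = None) -> Path:
    """Run the requested stages in canonical order; artifacts land under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    chosen = STAGES if stages is None else tuple(s for s in STAGES if s in set(stages))
    unknown = set(stages or ()) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    for stage in chosen:
        _require(out, stage)
        log.info("running stage %s", stage)
        _STAGE_FN[stage](cfg, out)
        _mark_done(out, stage, cfg)
    return out
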