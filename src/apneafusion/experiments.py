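"""Scaled-down end-to-end experiments on synthetic data.

These drive the property-style acceptance checks: branch label recovery,
fusion superiority on clean and noise-corrupted test sets, and Grad-CAM
localization of the desaturation region.  Sizes are deliberately small so a
full multi-seed replication fits in CPU minutes.
"""

from __future__ import annotations

import numpy as np

from .gradcam import gradcam, localization_score
from .ingest import SegmentationConfig, WindowSet, segment_record
from .models import DropoutMode, build_branch, build_fusion, ecg_branch_spec, spo2_branch_spec
from .quality import FilterConfig, bandpass
from .synthetic import SimConfig, desat_interval_s, simulate_pair
from .training import (
    NoiseProtocol,
    SplitPlan,
    TrainConfig,
    add_awgn,
    evaluate,
    evaluate_fusion,
    run_noise_protocol,
    split_indices,
    train_branch,
    train_fusion_head,
)

__all__ = ["build_synthetic_dataset", "run_scaled_experiment"]


def _concat(sets: list[WindowSet]) -> WindowSet:
    return WindowSet(
        np.concatenate([s.windows for s in sets]),
        np.concatenate([s.labels for s in sets]),
        sets[0].fs,
        sum((s.source_ids for s in sets), []),
        np.concatenate([s.start_times_s for s in sets]),
        sets[0].channel,
    )


def build_synthetic_dataset(
    seed: int,
    n_records: int = 10,
    duration_s: float = 220.0,
    seg: SegmentationConfig | None = None,
    **sim_overrides,
) -> tuple[WindowSet, WindowSet, dict[str, SimConfig]]:
    """Aligned, labeled (ECG, SpO2) window sets from ``n_records`` simulated pairs.

    Default simulation parameters are chosen for programmed separability:
    strong RR shortening during events and a short desaturation lag so both
    modalities carry the label inside the 11 s window.
    """
    seg = seg or SegmentationConfig()
    defaults = dict(
        duration_s=duration_s,
        apnea_event_rate=50.0,
        event_duration_s=(10.0, 20.0),
        desat_depth_pct=5.0,
        desat_lag_s=4.0,
        rr_apnea_modulation=0.30,
        noise_floor_sd=0.03,
    )
    defaults.update(sim_overrides)
    ecg_sets, spo2_sets = [], []
    meta: dict[str, SimConfig] = {}
    for r in range(n_records):
        cfg = SimConfig(seed=seed * 1009 + r, **defaults)
        ecg_rec, spo2_rec = simulate_pair(cfg)
        meta[ecg_rec.record_id] = cfg
        ecg_sets.append(segment_record(ecg_rec, seg))
        spo2_sets.append(segment_record(spo2_rec, seg))
    ecg_all, spo2_all = _concat(ecg_sets), _concat(spo2_sets)
    if not np.array_equal(ecg_all.labels, spo2_all.labels):
        raise AssertionError("paired segmentation produced inconsistent labels")
    return ecg_all, spo2_all, meta


def _desat_region_samples(
    start_s: float, window_s: float, fs: float, cfg: SimConfig
) -> tuple[int, int] | None:
    """The desaturation interval of the window's event, in window samples."""
    best = None
    for event in _events_for(cfg):
        lo, hi = desat_interval_s(event, cfg)
        a = max(lo, start_s) - start_s
        b = min(hi, start_s + window_s) - start_s
        if b - a > (0 if best is None else best[1] - best[0]):
            best = (a, b)
    if best is None:
        return None
    a = int(round(best[0] * fs))
    b = int(round(best[1] * fs))
    return (a, b) if b > a else None


def _events_for(cfg: SimConfig) -> list[tuple[float, float]]:
    # regenerate the deterministic event list without re-synthesizing samples
    from .synthetic import _place_events

    rng = np.random.default_rng(cfg.seed)
    return _place_events(cfg, rng)


def run_scaled_experiment(
    seed: int,
    n_records: int = 10,
    duration_s: float = 220.0,
    max_epochs: int = 10,
    noise_protocol: NoiseProtocol | None = None,
    gradcam_max_windows: int = 40,
) -> dict:
    """One seeded replication: train branches, fuse, score clean/noisy/Grad-CAM.

    Returns a flat dict of summary numbers (validation accuracies, epochs
    used, clean test metrics, per-scenario noisy F1, and the fraction of
    apneic SpO2 test windows whose importance concentrates inside the
    desaturation region).
    """
    ecg_all, spo2_all, meta = build_synthetic_dataset(seed, n_records, duration_s)
    ecg_all = bandpass(ecg_all, FilterConfig())

    plan = SplitPlan(seed=seed)
    tr, va, te = split_indices(ecg_all, plan)
    ecg_tr, ecg_va, ecg_te = (ecg_all.take(i) for i in (tr, va, te))
    spo2_tr, spo2_va, spo2_te = (spo2_all.take(i) for i in (tr, va, te))

    cfg = TrainConfig(max_epochs=max_epochs, stop_val_acc=0.95)
    ecg_model = build_branch(ecg_branch_spec(ecg_all.window_samples), seed=seed)
    hist_e = train_branch(ecg_model, ecg_tr, ecg_va, cfg, seed=seed)
    spo2_model = build_branch(spo2_branch_spec(spo2_all.window_samples), seed=seed + 1)
    hist_s = train_branch(spo2_model, spo2_tr, spo2_va, cfg, seed=seed + 1)

    fusion = build_fusion(ecg_model, spo2_model, fs=(ecg_all.fs, spo2_all.fs),
                          mode=DropoutMode.MISMATCHED_NEURONS, seed=seed)
    pre_checksum = fusion.checksum_branches()
    head_cfg = TrainConfig(max_epochs=60, patience=10)
    train_fusion_head(fusion, (ecg_tr, spo2_tr), (ecg_va, spo2_va), head_cfg, seed=seed)
    post_checksum = fusion.checksum_branches()

    m_ecg = evaluate(ecg_model, ecg_te)
    m_spo2 = evaluate(spo2_model, spo2_te)
    m_fusion = evaluate_fusion(fusion, (ecg_te, spo2_te))

    # Noise-robustness study: the branches stay as trained above; the fusion
    # head is (re)trained on train/val sets in which the protocol fraction of
    # windows is fully corrupted in both modalities.  Several independent
    # corruption draws are concatenated so the head sees enough noise
    # realizations to learn to discount corrupted inputs; it is then tested
    # at the test-set fraction.
    protocol = noise_protocol or NoiseProtocol(seed=seed)
    frac = protocol.train_val_fraction
    ecg_draws, spo2_draws = [], []
    for v in range(4):
        ev, idx = add_awgn(ecg_tr, protocol.snr_db, frac, seed=seed + 71 + 13 * v)
        sv, _ = add_awgn(spo2_tr, protocol.snr_db, frac, seed=seed + 72 + 13 * v, indices=idx)
        ecg_draws.append(ev)
        spo2_draws.append(sv)
    ecg_tr_n, spo2_tr_n = _concat(ecg_draws), _concat(spo2_draws)
    ecg_va_n, idx = add_awgn(ecg_va, protocol.snr_db, frac, seed=seed + 73)
    spo2_va_n, _ = add_awgn(spo2_va, protocol.snr_db, frac, seed=seed + 74, indices=idx)
    fusion_n = build_fusion(ecg_model, spo2_model, fs=(ecg_all.fs, spo2_all.fs),
                            mode=DropoutMode.MISMATCHED_NEURONS, seed=seed)
    noise_head_cfg = TrainConfig(max_epochs=30, patience=6)
    train_fusion_head(fusion_n, (ecg_tr_n, spo2_tr_n), (ecg_va_n, spo2_va_n),
                      noise_head_cfg, seed=seed)
    noisy = run_noise_protocol(
        {"ecg": ecg_model, "spo2": spo2_model}, fusion_n, (ecg_te, spo2_te), protocol
    )

    # Grad-CAM localization on correctly detected apneic SpO2 test windows
    window_s = spo2_te.window_samples / spo2_te.fs
    preds = spo2_model.predict(spo2_te.windows[:, None, :])
    ratios = []
    for i in np.flatnonzero((spo2_te.labels == 1) & (preds == 1)):
        sim_cfg = meta[spo2_te.source_ids[i]]
        region = _desat_region_samples(spo2_te.start_times_s[i], window_s, spo2_te.fs, sim_cfg)
        if region is None:
            continue
        a, b = region
        n = spo2_te.window_samples
        # require a non-trivial segment on each side: >= 2 s inside, >= 3 s outside
        if (b - a) < 2 * spo2_te.fs or (n - (b - a)) < 3 * spo2_te.fs:
            continue
        res = gradcam(spo2_model, spo2_te.windows[i], target_class=1)
        ratios.append(localization_score(res, region))
        if len(ratios) >= gradcam_max_windows:
            break

    return {
        "seed": seed,
        "n_pairs": len(ecg_all),
        "ecg_val_acc": max(h["val_acc"] for h in hist_e),
        "spo2_val_acc": max(h["val_acc"] for h in hist_s),
        "ecg_epochs": len(hist_e),
        "spo2_epochs": len(hist_s),
        "clean": {
            "ecg": m_ecg.to_dict(),
            "spo2": m_spo2.to_dict(),
            "fusion": m_fusion.to_dict(),
        },
        "noisy": {
            scen: {name: rep.to_dict() for name, rep in reps.items()}
            for scen, reps in noisy.items()
        },
        "branch_checksum_unchanged": bool(pre_checksum == post_checksum),
        "gradcam_ratios": ratios,
        "gradcam_frac_gt1": (
            float(np.mean([r > 1.0 for r in ratios])) if ratios else float("nan")
        ),
    }
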