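import numpy as np
import pytest

from apneafusion.ingest import WindowSet
from apneafusion.models import build_branch, build_fusion, spo2_branch_spec
from apneafusion.training import (
    MetricsReport,
    NoiseProtocol,
    NoiseScenario,
    SplitLevel,
    SplitPlan,
    TrainConfig,
    add_awgn,
    balance_and_augment,
    balance_and_augment_pair,
    evaluate,
    evaluate_fusion,
    run_noise_protocol,
    split_indices,
    train_branch,
    train_fusion_head,
)
from conftest import random_windowset


def _labeled_wset(rng, n_apnea, n_normal, width=88, fs=8.0):
    n = n_apnea + n_normal
    labels = np.concatenate([np.ones(n_apnea, dtype=np.int8),
                             np.zeros(n_normal, dtype=np.int8)])
    windows = rng.standard_normal((n, width)) + labels[:, None] * 2.0
    return WindowSet(windows, labels, fs, ["r"] * n, np.arange(n, dtype=float))


class TestBalanceAugment:
    def test_30_70_becomes_280(self, rng):
        out = balance_and_augment(_labeled_wset(rng, 30, 70), seed=0)
        assert len(out) == 280
        assert out.labels.sum() == 140

    def test_balanced_input_just_doubles(self, rng):
        out = balance_and_augment(_labeled_wset(rng, 50, 50), seed=0)
        assert len(out) == 200

    def test_flip_is_involution(self, rng):
        wset = _labeled_wset(rng, 10, 10)
        flipped_twice = wset.windows[:, ::-1][:, ::-1]
        np.testing.assert_array_equal(flipped_twice, wset.windows)

    def test_flipped_copies_present(self, rng):
        wset = _labeled_wset(rng, 20, 30)
        out = balance_and_augment(wset, seed=0)
        half = len(out) // 2
        np.testing.assert_array_equal(out.windows[half:], out.windows[:half][:, ::-1])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            balance_and_augment(_labeled_wset(rng, 0, 40), seed=0)

    def test_pair_version_keeps_alignment(self, rng):
        ecg = _labeled_wset(rng, 30, 70, width=1100, fs=100.0)
        spo2 = _labeled_wset(rng, 30, 70)
        ecg_b, spo2_b = balance_and_augment_pair(ecg, spo2, seed=1)
        assert len(ecg_b) == len(spo2_b) == 280
        np.testing.assert_array_equal(ecg_b.labels, spo2_b.labels)


class TestAwgn:
    def test_measured_snr_within_half_db(self, rng):
        wset = random_windowset(rng, n=50, width=500)
        noisy, idx = add_awgn(wset, -20.0, 1.0, seed=0)
        noise = noisy.windows - wset.windows
        p_sig = (wset.windows**2).mean(axis=1)
        p_noise = (noise**2).mean(axis=1)
        snr = 10.0 * np.log10(p_sig / p_noise)
        assert np.abs(snr + 20.0).max() < 0.5

    def test_exact_corruption_count(self, rng):
        wset = random_windowset(rng, n=10000, width=8)
        _, idx = add_awgn(wset, -20.0, 0.1142, seed=1)
        assert len(idx) == 1142
        assert len(np.unique(idx)) == 1142

    def test_fraction_zero_identity(self, rng):
        wset = random_windowset(rng, n=20, width=32)
        noisy, idx = add_awgn(wset, -20.0, 0.0, seed=2)
        assert idx.size == 0
        np.testing.assert_array_equal(noisy.windows, wset.windows)

    def test_forced_indices(self, rng):
        wset = random_windowset(rng, n=20, width=32)
        noisy, idx = add_awgn(wset, -20.0, 0.1, seed=3, indices=[4, 7])
        np.testing.assert_array_equal(idx, [4, 7])
        untouched = np.setdiff1d(np.arange(20), idx)
        np.testing.assert_array_equal(noisy.windows[untouched], wset.windows[untouched])

    def test_zero_power_window_rejected(self, rng):
        wset = random_windowset(rng, n=5, width=16)
        wset.windows[2] = 0.0
        with pytest.raises(ValueError, match="zero-power"):
            add_awgn(wset, -20.0, 1.0, seed=0)


class TestMetrics:
    def test_fixed_confusion_matrix(self):
        rep = MetricsReport(tp=3, fp=1, fn=1, tn=5)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(5.0 / 6.0)
        assert rep.f1 == pytest.approx(0.75)

    def test_all_correct(self):
        rep = MetricsReport.from_predictions(np.array([0, 1, 1]), np.array([0, 1, 1]))
        assert (rep.accuracy, rep.precision, rep.recall, rep.specificity, rep.f1) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_f1_is_harmonic_mean(self):
        rep = MetricsReport(tp=7, fp=2, fn=4, tn=11)
        p, r = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_counts_sum_to_n(self):
        rep = MetricsReport(tp=3, fp=1, fn=1, tn=5)
        assert rep.n == 10

    def test_against_brute_force_recount(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        rep = MetricsReport.from_predictions(y, p)
        # independent counting oracle
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (tp, fp, fn, tn)
        assert rep.accuracy == (tp + tn) / 200

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MetricsReport.from_predictions(np.array([]), np.array([]))


class TestSplit:
    def test_record_level_partitions_sources(self, rng):
        sets = []
        for r in range(10):
            w = random_windowset(rng, n=20)
            w = w.replace(source_ids=[f"rec{r}"] * 20)
            sets.append(w)
        allw = WindowSet(
            np.concatenate([s.windows for s in sets]),
            np.concatenate([s.labels for s in sets]),
            100.0,
            sum((s.source_ids for s in sets), []),
            np.concatenate([s.start_times_s for s in sets]),
        )
        tr, va, te = split_indices(allw, SplitPlan(seed=0))
        groups = [set(allw.source_ids[i] for i in idx) for idx in (tr, va, te)]
        assert len(tr) == 160 and len(va) == 20 and len(te) == 20
        assert not (groups[0] & groups[1]) and not (groups[0] & groups[2])

    def test_segment_level_counts(self, rng):
        w = random_windowset(rng, n=100)
        tr, va, te = split_indices(w, SplitPlan(level=SplitLevel.SEGMENT, seed=1))
        assert len(tr) == 80 and len(va) == 10 and len(te) == 10
        assert len(set(tr) | set(va) | set(te)) == 100


def _training_data(rng, n=120, width=88):
    train = _labeled_wset(rng, n // 3, 2 * n // 3, width=width)
    val = _labeled_wset(np.random.default_rng(99), 15, 30, width=width)
    return train, val


class TestTrainBranch:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = build_branch(spo2_branch_spec(), seed=0)
        before = model.state_dict()
        train, val = _training_data(rng)
        hist = train_branch(model, train, val, TrainConfig(max_epochs=0), seed=0)
        assert hist == []
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_same_seed_identical_parameters(self, rng):
        train, val = _training_data(rng)
        cfg = TrainConfig(max_epochs=2, restore_best=False)
        states = []
        for _ in range(2):
            model = build_branch(spo2_branch_spec(), seed=4)
            train_branch(model, train, val, cfg, seed=11)
            states.append(model.state_dict())
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])

    def test_history_records_epochs(self, rng):
        train, val = _training_data(rng)
        model = build_branch(spo2_branch_spec(), seed=0)
        hist = train_branch(model, train, val, TrainConfig(max_epochs=3, patience=10), seed=0)
        assert [h["epoch"] for h in hist] == list(range(len(hist)))
        assert len(hist) <= 3
        assert all(np.isfinite(h["val_loss"]) for h in hist)


@pytest.fixture(scope="module")
def fusion_setup():
    rng = np.random.default_rng(0)
    e_tr = _labeled_wset(rng, 40, 80, width=1100, fs=100.0)
    s_tr = _labeled_wset(rng, 40, 80, width=88, fs=8.0)
    s_tr = s_tr.replace(labels=e_tr.labels.copy())
    e_va = _labeled_wset(rng, 10, 20, width=1100, fs=100.0)
    s_va = _labeled_wset(rng, 10, 20, width=88, fs=8.0)
    s_va = s_va.replace(labels=e_va.labels.copy())
    from apneafusion.models import ecg_branch_spec

    em = build_branch(ecg_branch_spec(), seed=0)
    sm = build_branch(spo2_branch_spec(), seed=1)
    cfg = TrainConfig(max_epochs=1)
    train_branch(em, e_tr, e_va, cfg, seed=0)
    train_branch(sm, s_tr, s_va, cfg, seed=1)
    fusion = build_fusion(em, sm, seed=2)
    return em, sm, fusion, (e_tr, s_tr), (e_va, s_va)


class TestFusionTrainingAndProtocol:

    def test_frozen_parameters_bit_identical(self, fusion_setup):
        em, sm, fusion, train_pair, val_pair = fusion_setup
        before = {f"t{i}.{k}": v.copy() for i, t in enumerate(fusion.trunks)
                  for k, v in t.state_dict().items()}
        train_fusion_head(fusion, train_pair, val_pair, TrainConfig(max_epochs=2), seed=0)
        after = {f"t{i}.{k}": v for i, t in enumerate(fusion.trunks)
                 for k, v in t.state_dict().items()}
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_protocol_fraction_zero_equals_clean(self, fusion_setup):
        em, sm, fusion, _, val_pair = fusion_setup
        protocol = NoiseProtocol(test_fraction=0.0, seed=1)
        reports = run_noise_protocol({"ecg": em, "spo2": sm}, fusion, val_pair, protocol)
        clean_e = evaluate(em, val_pair[0]).to_dict()
        clean_f = evaluate_fusion(fusion, val_pair).to_dict()
        for scen in reports:
            assert reports[scen]["ecg"].to_dict() == clean_e
            assert reports[scen]["fusion"].to_dict() == clean_f

    def test_scenario_draws_differ(self, fusion_setup):
        em, sm, fusion, _, val_pair = fusion_setup
        protocol = NoiseProtocol(test_fraction=0.3, seed=5)
        _, idx_e = add_awgn(val_pair[0], protocol.snr_db, 0.3, seed=protocol.seed + 1000)
        _, idx_s = add_awgn(val_pair[1], protocol.snr_db, 0.3, seed=protocol.seed + 2000)
        assert list(idx_e) != list(idx_s)

    def test_both_scenario_shares_indices(self, fusion_setup):
        em, sm, fusion, _, (e_va, s_va) = fusion_setup
        protocol = NoiseProtocol(test_fraction=0.3, seed=5,
                                 scenarios=(NoiseScenario.BOTH,))
        reports = run_noise_protocol({"ecg": em, "spo2": sm}, fusion, (e_va, s_va), protocol)
        assert set(reports) == {"BOTH"}

    def test_misaligned_pair_rejected(self, fusion_setup):
        em, sm, fusion, train_pair, val_pair = fusion_setup
        bad = val_pair[1].replace(labels=1 - val_pair[1].labels)
        with pytest.raises(ValueError, match="misaligned"):
            run_noise_protocol({"ecg": em, "spo2": sm}, fusion, (val_pair[0], bad))
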