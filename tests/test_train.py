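"""Losses, freezing, folds, event-F1 callback and domain-gap metrics."""

import math

import numpy as np
import pytest

from apneaseg.events import EventInterval
from apneaseg.nn import BatchNorm1d, Tensor
from apneaseg.postproc import PostprocConfig
from apneaseg.segnet import build_model
from apneaseg.train import (
    LossConfig, TrainConfig, combined_loss, dice_loss, domain_gap_report,
    event_f1_callback, freeze_layers, stratified_folds, weighted_bce,
)


class TestLosses:
    def test_dice_perfect_overlap_zero(self):
        y = np.array([1.0, 0.0, 1.0, 1.0])
        assert float(dice_loss(y, y).data) == pytest.approx(0.0, abs=1e-6)

    def test_dice_all_empty_epsilon_rescue(self):
        z = np.zeros(8)
        assert float(dice_loss(z, z).data) == pytest.approx(0.0, abs=1e-6)

    def test_dice_hand_value(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.array([1.0, 0.0, 0.0, 0.0])
        val = float(dice_loss(y, p, epsilon=0.0).data)
        assert val == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_bce_closed_form(self):
        y = np.ones(10)
        p = np.full(10, 0.5)
        val = float(weighted_bce(y, p, w_pos=2.0, w_neg=1.0).data)
        assert val == pytest.approx(2.0 * math.log(2.0), rel=1e-5)

    def test_bce_zero_at_perfect_prediction(self):
        y = np.array([1.0, 0.0, 1.0])
        assert float(weighted_bce(y, y).data) < 1e-5

    def test_bce_equals_unweighted_reference(self, rng):
        """Independent implementation cross-check at w_pos = w_neg = 1."""
        y = (rng.uniform(size=50) < 0.4).astype(float)
        p = rng.uniform(0.05, 0.95, size=50)
        ref = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        val = float(weighted_bce(y, p, w_pos=1.0, w_neg=1.0).data)
        assert val == pytest.approx(ref, rel=1e-5)

    def test_combined_boundaries_and_mixture(self, rng):
        y = (rng.uniform(size=20) < 0.3).astype(float)
        p = rng.uniform(0.1, 0.9, size=20)
        d = float(dice_loss(y, p, 1e-6).data)
        b = float(weighted_bce(y, p).data)
        assert float(combined_loss(y, p, LossConfig(alpha_mix=1.0)).data) \
            == pytest.approx(d, rel=1e-5)
        assert float(combined_loss(y, p, LossConfig(alpha_mix=0.0)).data) \
            == pytest.approx(b, rel=1e-5)
        assert float(combined_loss(y, p, LossConfig(alpha_mix=0.8)).data) \
            == pytest.approx(0.8 * d + 0.2 * b, rel=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros(4), np.zeros(5))

    def test_losses_match_closed_form_on_random_tensors(self, rng):
        """Oracle equivalence on random small tensors."""
        eps, delta = 1e-6, 1e-7
        for _ in range(20):
            shape = (int(rng.integers(1, 4)), int(rng.integers(2, 30)))
            y = (rng.uniform(size=shape) < 0.3).astype(float)
            p = rng.uniform(0.02, 0.98, size=shape).astype(np.float32)
            p64 = p.astype(float)
            dice_ref = 1 - (2 * np.sum(y * p64) + eps) / (
                np.sum(y) + np.sum(p64) + eps)
            pc = np.clip(p64, delta, 1 - delta)
            bce_ref = -np.mean(2.0 * y * np.log(pc)
                               + 1.0 * (1 - y) * np.log(1 - pc))
            assert float(dice_loss(y, p, eps).data) == pytest.approx(
                dice_ref, abs=1e-6)
            assert float(weighted_bce(y, p).data) == pytest.approx(
                bce_ref, abs=1e-5)


class TestFreezing:
    def test_floor_arithmetic(self, micro_cfg):
        model = build_model(micro_cfg, seed=0)
        layers = model.layer_list()
        L = len(layers)
        freeze_layers(model, 0.6, bn_freeze=False)
        frozen = [l for l in layers if not l.trainable]
        assert len(frozen) == math.floor(0.6 * L)
        assert frozen == layers[:len(frozen)]

    def test_rho_zero_all_trainable(self, micro_cfg):
        model = build_model(micro_cfg, seed=0)
        freeze_layers(model, 0.0, bn_freeze=False)
        assert all(l.trainable for l in model.layer_list())

    def test_rho_one_rejected(self, micro_cfg):
        with pytest.raises(ValueError):
            freeze_layers(build_model(micro_cfg, seed=0), 1.0)
        with pytest.raises(ValueError):
            TrainConfig(freeze_ratio=1.0)

    def test_frozen_params_keep_values_and_zero_grads(self, micro_cfg, rng):
        from apneaseg.nn import Adam
        model = build_model(micro_cfg, seed=0)
        freeze_layers(model, 0.6, bn_freeze=True)
        frozen_params = [(n, p.data.copy())
                         for n, p in model.named_parameters()
                         if not p.requires_grad]
        assert frozen_params
        opt = Adam(model.trainable_parameters(), lr=1e-2)
        x = rng.normal(size=(2, micro_cfg.input_len, 2))
        y = (rng.uniform(size=(2, micro_cfg.input_len, 1)) < 0.3).astype(float)
        for _ in range(2):
            model.zero_grad()
            combined_loss(y, model.forward(x), LossConfig()).backward()
            opt.step()
        current = dict(model.named_parameters())
        for name, before in frozen_params:
            assert current[name].grad is None
            assert np.array_equal(current[name].data, before), name

    def test_bn_freeze_stats_unchanged_during_training(self, micro_cfg, rng):
        model = build_model(micro_cfg, seed=0)
        freeze_layers(model, 0.0, bn_freeze=True)
        bns = [m for m in model.modules() if isinstance(m, BatchNorm1d)]
        before = [(bn._buffers["running_mean"].copy(),
                   bn._buffers["running_var"].copy()) for bn in bns]
        model.train()
        model.forward(rng.normal(size=(4, micro_cfg.input_len, 2)))
        for bn, (rm, rv) in zip(bns, before):
            assert np.array_equal(bn._buffers["running_mean"], rm)
            assert np.array_equal(bn._buffers["running_var"], rv)


class TestStratifiedFolds:
    def test_target_cohort_composition(self):
        """17/12/3/3 nights into K=3: 5/4/1/1 once and 6/4/1/1 twice."""
        sev = {}
        nid = 0
        for cls, count in enumerate([17, 12, 3, 3]):
            for _ in range(count):
                sev[f"n{nid:02d}"] = cls
                nid += 1
        plan = stratified_folds(sev, K=3, seed=0)
        per_fold = []
        for k in range(3):
            nights = plan.fold_nights(k)
            counts = [sum(sev[n] == c for n in nights) for c in range(4)]
            per_fold.append(tuple(counts))
        assert sorted(per_fold) == [(5, 4, 1, 1), (6, 4, 1, 1), (6, 4, 1, 1)]

    def test_partition_property(self):
        sev = {f"n{i}": i % 4 for i in range(23)}
        plan = stratified_folds(sev, K=3, seed=5)
        all_nights = sorted(n for k in range(3) for n in plan.fold_nights(k))
        assert all_nights == sorted(sev)

    def test_single_fold(self):
        sev = {"a": 0, "b": 1}
        plan = stratified_folds(sev, K=1, seed=0)
        assert plan.fold_nights(0) == ["a", "b"]

    def test_deterministic_per_seed(self):
        sev = {f"n{i}": i % 3 for i in range(20)}
        a = stratified_folds(sev, K=3, seed=7)
        b = stratified_folds(sev, K=3, seed=7)
        c = stratified_folds(sev, K=3, seed=8)
        assert a.assignments == b.assignments
        assert a.assignments != c.assignments

    def test_k_exceeding_nights_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds({"a": 0}, K=3)

    def test_class_balance_within_one(self, rng):
        for _ in range(10):
            sev = {f"n{i}": int(rng.integers(0, 4))
                   for i in range(int(rng.integers(6, 40)))}
            K = 3
            if len(sev) < K:
                continue
            plan = stratified_folds(sev, K=K, seed=int(rng.integers(100)))
            for c in set(sev.values()):
                counts = [sum(sev[n] == c for n in plan.fold_nights(k))
                          for k in range(K)]
                assert max(counts) - min(counts) <= 1


class TestEventF1Callback:
    def test_all_zero_model_gives_zero_f1(self, trained_tiny, micro_cfg):
        # fresh untrained-ish model biased to zero output
        model = build_model(trained_tiny["cfg"], seed=99)
        model.head.bias.data[...] = -20.0
        f1 = event_f1_callback(model, trained_tiny["val"], PostprocConfig())
        assert f1 == 0.0

    def test_empty_validation_rejected(self, trained_tiny):
        with pytest.raises(ValueError):
            event_f1_callback(trained_tiny["model"], [], PostprocConfig())


class TestDomainGap:
    def test_identical_sets_no_gap(self, rng):
        f = rng.normal(size=(60, 8))
        rep = domain_gap_report(f, f.copy(), k=5)
        assert abs(rep.mmd2) < 1e-6
        assert rep.coral == pytest.approx(0.0, abs=1e-12)

    def test_separated_clusters_maximal_gap(self, rng):
        a = rng.normal(0.0, 0.5, size=(60, 6))
        b = rng.normal(10.0, 0.5, size=(60, 6))
        rep = domain_gap_report(a, b, k=5)
        assert rep.probe_auc > 0.99
        assert rep.knn_mixing < 0.01
        assert rep.mmd2 > 0.5

    def test_random_split_confused(self, rng):
        pool = rng.normal(size=(160, 6))
        rep = domain_gap_report(pool[:80], pool[80:], k=10)
        assert abs(rep.probe_auc - 0.5) < 0.12
        # expected opposite-domain fraction ~ 80/159
        assert rep.knn_mixing == pytest.approx(80 / 159, abs=0.08)
        # V-statistic bias is O(1/n): small but nonzero at n = 80
        assert abs(rep.mmd2) < 0.05

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            domain_gap_report(rng.normal(size=(5, 3)),
                              rng.normal(size=(5, 3)), k=10)
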