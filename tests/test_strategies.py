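"""Augmentations, NT-Xent, MoCo mechanics, pretraining and fine-tuning."""

import numpy as np
import pytest

from brugadanet import nn, preprocess
from brugadanet.backbone import load_checkpoint, parameter_checksums
from brugadanet.containers import BeatDataset
from brugadanet.strategies import (AugmentationParams, ContrastiveConfig,
                                   TrainConfig, augment_baseline_drift,
                                   augment_gaussian_noise,
                                   augmentation_ablation, finetune,
                                   momentum_update, nt_xent_loss,
                                   pretrain_moco_v2, pretrain_simclr,
                                   pretrain_supervised)
from brugadanet.synth import default_params, generate_record, measure_brugada_features
from tests.conftest import SMALL_BACKBONE


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

class TestAugmentations:
    def test_zero_amplitude_is_identity(self, rng):
        beat = rng.normal(size=(12, 100))
        p0 = AugmentationParams(drift_amplitude_range=(0.0, 0.0),
                                noise_sd_range=(0.0, 0.0))
        assert np.array_equal(augment_baseline_drift(beat, p0, rng), beat)
        assert np.array_equal(augment_gaussian_noise(beat, p0, rng), beat)

    def test_drift_residual_is_shared_low_frequency_offset(self):
        rng = np.random.default_rng(0)
        beat = rng.normal(size=(12, 100))
        p = AugmentationParams()
        out = augment_baseline_drift(beat, p, rng)
        res = out - beat
        # shared across leads
        assert np.allclose(res, res[0][None, :])
        # low frequency: the drawn drift is at most half a cycle per window,
        # so (with spectral leakage) the lowest DFT bins hold nearly all energy
        spec = np.abs(np.fft.rfft(res[0])) ** 2
        assert spec[:5].sum() / spec.sum() > 0.9

    def test_noise_residual_statistics(self):
        rng = np.random.default_rng(1)
        beat = np.zeros((12, 100))
        sd = 0.03
        p = AugmentationParams(noise_sd_range=(sd, sd))
        res = augment_gaussian_noise(beat, p, rng) - beat
        assert abs(res.std() - sd) < 0.1 * sd
        assert abs(res.mean()) < 3 * sd / np.sqrt(res.size)

    def test_same_rng_state_reproducible(self):
        beat = np.random.default_rng(2).normal(size=(12, 100))
        p = AugmentationParams()
        a = augment_baseline_drift(beat, p, np.random.default_rng(5))
        b = augment_baseline_drift(beat, p, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_augmentation_preserves_brugada_features(self):
        p = default_params("brugada_type1", j_point_amplitude_mV=0.3)
        rec = preprocess.resample_to_target(generate_record(p, 500, 10.0, 0))
        beats = preprocess.extract_beats(rec, rec.true_r_peak_samples)
        aug = AugmentationParams()
        rng = np.random.default_rng(3)
        measured = []
        for b in beats:
            v = augment_gaussian_noise(
                augment_baseline_drift(b.values, aug, rng), aug, rng)
            b2 = type(b)(v, b.patient_id, b.record_id, b.label, b.r_peak_sample)
            measured.append(measure_brugada_features(b2)[0])
        # documented tolerance under default augmentation ranges
        assert abs(np.median(measured) - 0.3) < 0.2 * 0.3

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentationParams(noise_sd_range=(0.1, 0.01))
        with pytest.raises(ValueError):
            AugmentationParams(enabled_ops=("time_warp",))


# ---------------------------------------------------------------------------
# NT-Xent
# ---------------------------------------------------------------------------

def _brute_force_nt_xent(e: np.ndarray, tau: float) -> float:
    z = e / np.linalg.norm(e, axis=1, keepdims=True)
    two_n = len(z)
    n = two_n // 2
    total = 0.0
    for i in range(two_n):
        pos = (i + n) % two_n
        logits = np.array([z[i] @ z[j] / tau for j in range(two_n) if j != i])
        target = z[i] @ z[pos] / tau
        total += -(target - np.log(np.sum(np.exp(logits))))
    return total / two_n


class TestNtXent:
    def test_single_pair_no_negatives_zero_loss(self):
        e = nn.Tensor(np.array([[1.0, 0.0], [0.6, 0.8]]))
        assert float(nt_xent_loss(e, 1.0).data) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_two_pairs_orthogonal(self):
        # positives identical, negatives orthogonal, tau=1:
        # per anchor loss = -log(e / (e + 2))
        e = nn.Tensor(np.array([[1.0, 0.0], [0.0, 1.0],
                                [1.0, 0.0], [0.0, 1.0]]))
        expected = -np.log(np.e / (np.e + 2.0))
        assert float(nt_xent_loss(e, 1.0).data) == pytest.approx(expected,
                                                                 abs=1e-6)

    def test_pair_order_symmetry(self, rng):
        e = rng.normal(size=(8, 5))
        swapped = np.concatenate([e[4:], e[:4]])
        a = float(nt_xent_loss(nn.Tensor(e), 0.5).data)
        b = float(nt_xent_loss(nn.Tensor(swapped), 0.5).data)
        assert a == pytest.approx(b, abs=1e-6)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_matches_brute_force(self, n, rng):
        e = rng.normal(size=(2 * n, 6)).astype(np.float32)
        ours = float(nt_xent_loss(nn.Tensor(e), 0.5).data)
        brute = _brute_force_nt_xent(e.astype(np.float64), 0.5)
        assert abs(ours - brute) < 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            nt_xent_loss(nn.Tensor(np.ones((3, 4))), 0.5)  # odd rows
        with pytest.raises(ValueError):
            nt_xent_loss(nn.Tensor(np.ones((4, 4))), -1.0)


# ---------------------------------------------------------------------------
# MoCo mechanics
# ---------------------------------------------------------------------------

class TestMoco:
    @pytest.mark.parametrize("m", [0.0, 0.25, 0.999, 1.0])
    def test_momentum_update_exact_convex_combination(self, m):
        from brugadanet.backbone import attach_head, build_backbone
        q = attach_head(build_backbone(SMALL_BACKBONE, seed=0), "projection",
                        8, seed=1)
        k = attach_head(build_backbone(SMALL_BACKBONE, seed=2), "projection",
                        8, seed=3)
        expected = [m * pk.data + (1 - m) * pq.data
                    for pk, pq in zip(k.parameters(), q.parameters())]
        momentum_update(k, q, m)
        for pk, exp in zip(k.parameters(), expected):
            assert np.allclose(pk.data, exp, atol=0)

    def test_queue_length_bookkeeping(self, tiny_beats):
        cfg = ContrastiveConfig(framework="moco_v2", batch_size=10,
                                queue_size=30, epochs=2, seed=0)
        X = tiny_beats.beats[:45]
        report, _ = pretrain_moco_v2(X, cfg, AugmentationParams(),
                                     SMALL_BACKBONE)
        hist = report.extras["queue_length_history"]
        expected = [min((i + 1) * 10, 30) for i in range(len(hist))]
        assert hist == expected

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ContrastiveConfig(framework="moco_v2", queue_size=0)
        with pytest.raises(ValueError):
            ContrastiveConfig(framework="moco_v2", batch_size=32,
                              queue_size=100)
        with pytest.raises(ValueError):
            ContrastiveConfig(batch_size=1)


# ---------------------------------------------------------------------------
# Pretraining runs
# ---------------------------------------------------------------------------

class TestSimclr:
    def test_reproducible_and_head_discarded(self, tiny_beats, tmp_path):
        cfg = ContrastiveConfig(batch_size=16, epochs=2, seed=11)
        X = tiny_beats.beats[:64]
        r1, _ = pretrain_simclr(X, cfg, AugmentationParams(), SMALL_BACKBONE,
                                checkpoint_path=tmp_path / "a")
        r2, _ = pretrain_simclr(X, cfg, AugmentationParams(), SMALL_BACKBONE)
        assert r1.loss_curve == pytest.approx(r2.loss_curve, abs=1e-6)
        loaded = load_checkpoint(tmp_path / "a", SMALL_BACKBONE)
        assert loaded.head is None  # f(.) only; g(.) discarded

    def test_loss_improves_on_separable_beats(self, tiny_beats):
        cfg = ContrastiveConfig(batch_size=16, epochs=5, seed=1)
        X = tiny_beats.beats[:96]
        report, _ = pretrain_simclr(X, cfg, AugmentationParams(),
                                    SMALL_BACKBONE)
        assert report.loss_curve[-1] < report.loss_curve[0]


class TestSupervisedPretrain:
    def test_five_class_head_arity(self, tiny_beats):
        labels = np.array(["a", "b", "c", "d", "e"] * 12)
        _, bundle = pretrain_supervised(
            tiny_beats.beats[:60], labels, "five_class", SMALL_BACKBONE,
            seed=0, train_config=TrainConfig(epochs=1, batch_size=16, seed=0))
        assert bundle.head.w.data.shape[1] == 5

    def test_single_class_rejected(self, tiny_beats):
        with pytest.raises(ValueError):
            pretrain_supervised(tiny_beats.beats[:10], np.array(["x"] * 10),
                                "rbbb_vs_normal", SMALL_BACKBONE, seed=0)

    def test_unknown_task_rejected(self, tiny_beats):
        with pytest.raises(ValueError):
            pretrain_supervised(tiny_beats.beats[:10],
                                np.array(["a", "b"] * 5), "weird",
                                SMALL_BACKBONE, seed=0)


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def _partitions(beats: BeatDataset):
    pats = np.array(sorted(set(beats.patient_ids)))
    val = set(pats[::5])
    fit = set(pats) - val
    sub = lambda ids: beats.subset(np.isin(beats.patient_ids.astype(str),
                                           sorted(ids)))
    return sub(fit), sub(val)


class TestFinetune:
    def test_baseline_is_random_init_unfrozen(self, tiny_beats):
        fit, val = _partitions(tiny_beats)
        report, bundle = finetune(None, fit, val, SMALL_BACKBONE, seed=0,
                                  freeze_final_blocks=None,
                                  train_config=TrainConfig(epochs=2,
                                                           batch_size=16,
                                                           seed=0))
        assert report.strategy == "baseline"
        assert all(bundle.trainable_mask)

    def test_frozen_checksums_stable_through_finetune(self, tiny_beats,
                                                      tmp_path):
        fit, val = _partitions(tiny_beats)
        labels = np.where(np.char.startswith(
            fit.labels.astype(str), "brugada"), "pos", "neg")
        _, pre = pretrain_supervised(
            fit.beats, labels, "rbbb_vs_normal", SMALL_BACKBONE, seed=0,
            train_config=TrainConfig(epochs=1, batch_size=16, seed=0),
            checkpoint_path=tmp_path / "ck")
        _, bundle = finetune(tmp_path / "ck", fit, val, SMALL_BACKBONE,
                             seed=1, freeze_final_blocks=2,
                             train_config=TrainConfig(epochs=2, batch_size=16,
                                                      seed=1))
        pre_sums = parameter_checksums(load_checkpoint(tmp_path / "ck",
                                                       SMALL_BACKBONE))
        post_sums = parameter_checksums(bundle)
        for g in ("block1", "block2"):
            assert post_sums[g] == pre_sums[g]
        assert post_sums[f"block{SMALL_BACKBONE.n_dense_blocks}"] != pre_sums[
            f"block{SMALL_BACKBONE.n_dense_blocks}"]

    def test_single_class_training_set_rejected(self, tiny_beats):
        fit, val = _partitions(tiny_beats)
        normals = fit.subset(fit.labels.astype(str) == "normal")
        with pytest.raises(ValueError):
            finetune(None, normals, val, SMALL_BACKBONE, seed=0,
                     train_config=TrainConfig(epochs=1, seed=0))


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

class TestAblation:
    def test_rows_and_combined(self, tiny_beats):
        augs = {
            "drift": AugmentationParams(enabled_ops=("baseline_drift",)),
            "noise": AugmentationParams(enabled_ops=("gaussian_noise",)),
        }
        cfg = ContrastiveConfig(batch_size=16, epochs=1, seed=0)
        calls = []

        def fake_eval(bundle):
            calls.append(bundle)
            return dict(auc=0.5)

        table = augmentation_ablation("simclr", tiny_beats.beats[:48], augs,
                                      fake_eval, cfg, SMALL_BACKBONE)
        assert list(table["augmentation"]) == ["drift", "noise", "combined"]
        assert len(calls) == 3

    def test_identity_augmentation_warns(self, tiny_beats):
        augs = {"none": AugmentationParams(
            drift_amplitude_range=(0.0, 0.0), enabled_ops=("baseline_drift",))}
        cfg = ContrastiveConfig(batch_size=16, epochs=1, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            augmentation_ablation("simclr", tiny_beats.beats[:32], augs,
                                  lambda b: dict(auc=0.5), cfg,
                                  SMALL_BACKBONE, include_combined=False)
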