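"""Metric report and paired-comparison statistics against independent
oracles (brute-force AUC, jackknife variance, binomial enumeration,
hand-computed step-down)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brugadanet.containers import BeatDataset
from brugadanet.evalstats import (METRIC_NAMES, SingleClassError,
                                  compute_metrics, delong_auc_variance,
                                  delong_test, holm_adjust, learning_curve,
                                  mcnemar_test, mimic_stress_test,
                                  paired_bootstrap, summarise_cv)


class TestComputeMetrics:
    def test_perfect_scores(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([1.0, 1.0, 0.0, 0.0])
        r = compute_metrics(y, s)
        assert (r.accuracy, r.auc, r.brier) == (1.0, 1.0, 0.0)
        assert r.f1 == 1.0

    def test_hand_confusion_matrix(self):
        r = compute_metrics(np.array([1, 1, 0, 0]),
                            np.array([0.9, 0.4, 0.6, 0.1]))
        assert r.accuracy == 0.5
        assert r.sensitivity == 0.5
        assert r.specificity == 0.5
        assert r.f1 == 0.5

    def test_constant_half_score_brier(self):
        y = np.array([1, 0] * 10)
        r = compute_metrics(y, np.full(20, 0.5))
        assert r.brier == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            compute_metrics(np.ones(5), np.linspace(0, 1, 5))


class TestDelong:
    def test_identical_scores_give_null_result(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.uniform(size=40)
        auc_a, auc_b, z, p = delong_test(y, s, s)
        assert auc_a == auc_b
        assert z == 0.0
        assert p == 1.0

    def test_auc_equals_pairwise_count_with_ties(self, rng):
        y = np.array([1] * 8 + [0] * 12)
        s = np.round(rng.uniform(size=20), 1)  # force ties
        auc, _ = delong_auc_variance(y, s)
        pos, neg = s[y == 1], s[y == 0]
        brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                         for a in pos for b in neg])
        assert auc == pytest.approx(brute, abs=1e-12)

    def test_variance_matches_jackknife(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = rng.uniform(size=n) + 0.5 * y
        _, var = delong_auc_variance(y, s)

        def auc_of(idx):
            return delong_auc_variance(y[idx], s[idx])[0]

        loo = np.array([auc_of(np.delete(np.arange(n), i)) for i in range(n)])
        var_jack = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert abs(var - var_jack) / var_jack < 0.10

    def test_delong_auc_consistent_with_metric_report(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.uniform(size=60)
        auc, _ = delong_auc_variance(y, s)
        assert abs(auc - compute_metrics(y, s).auc) < 1e-9


class TestMcnemar:
    def test_identical_predictions(self):
        y = np.array([0, 1, 1, 0])
        p = np.array([0, 1, 0, 0])
        b, c, pv = mcnemar_test(y, p, p)
        assert (b, c, pv) == (0, 0, 1.0)

    def test_one_sided_discordance_closed_form(self):
        y = np.ones(10, dtype=int)
        pred_a = np.ones(10, dtype=int)
        pred_b = np.zeros(10, dtype=int)
        b, c, p = mcnemar_test(y, pred_a, pred_b)
        assert (b, c) == (10, 0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_exact_branch_matches_binomial_enumeration(self):
        for b in range(13):
            for c in range(13 - b):
                if b + c == 0:
                    continue
                n = b + c
                y = np.ones(n, dtype=int)
                pred_a = np.concatenate([np.ones(b), np.zeros(c)]).astype(int)
                pred_b = np.concatenate([np.zeros(b), np.ones(c)]).astype(int)
                _, _, p = mcnemar_test(y, pred_a, pred_b)
                k = min(b, c)
                expected = min(1.0, 2 * stats.binom.cdf(k, n, 0.5))
                assert p == pytest.approx(expected, rel=1e-9), (b, c)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_down(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_order_preserved_and_monotone(self, rng):
        p = rng.uniform(size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestPairedBootstrap:
    def test_identical_models_zero_differences(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.uniform(size=100)
        res = paired_bootstrap(y, s, s, n_resamples=200, seed=0)
        assert np.all(res.table["mean_diff"] == 0.0)
        assert np.all(res.table["ci_low"] <= 0.0)
        assert np.all(res.table["ci_high"] >= 0.0)

    def test_seeded_reproducibility(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        a, b = rng.uniform(size=80), rng.uniform(size=80)
        r1 = paired_bootstrap(y, a, b, n_resamples=200, seed=5)
        r2 = paired_bootstrap(y, a, b, n_resamples=200, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_small_resample_count_warns(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.uniform(size=40)
        with pytest.warns(UserWarning, match="small"):
            paired_bootstrap(y, s, s, n_resamples=50, seed=0)


class TestSummariseCv:
    def test_identical_folds_zero_spread(self):
        rep = compute_metrics(np.array([1, 1, 0, 0]),
                              np.array([0.9, 0.8, 0.2, 0.1]))
        table = summarise_cv([rep] * 4)
        assert np.allclose(table["sd"], 0.0)
        assert np.allclose(table["ci_low"], table["ci_high"])

    def test_hand_arithmetic_and_symmetry(self):
        reps = []
        for auc in (0.90, 0.92, 0.94):
            r = compute_metrics(np.array([1, 1, 0, 0]),
                                np.array([0.9, 0.8, 0.2, 0.1]))
            r.auc = auc
            reps.append(r)
        row = summarise_cv(reps).set_index("metric").loc["auc"]
        assert row["mean"] == pytest.approx(0.92)
        assert row["sd"] == pytest.approx(0.02)
        assert row["ci_high"] - row["mean"] == pytest.approx(
            row["mean"] - row["ci_low"])

    def test_single_fold_rejected(self):
        rep = compute_metrics(np.array([1, 0]), np.array([0.9, 0.1]))
        with pytest.raises(ValueError):
            summarise_cv([rep])


def _mimic_dataset(rng):
    labels, recs = [], []
    for cat, n in [("rbbb", 5), ("early_repol", 4), ("anterior_stemi", 3),
                   ("hcm_like", 2)]:
        for i in range(n):
            for _ in range(3):  # 3 beats per record
                labels.append(cat)
                recs.append(f"{cat}{i}")
    n_beats = len(labels)
    return BeatDataset(rng.normal(size=(n_beats, 12, 10)),
                       np.array(labels, dtype=object),
                       np.array(recs, dtype=object),
                       np.array(recs, dtype=object))


class TestMimicStressTest:
    def test_always_negative_zero_fpr(self, rng):
        ds = _mimic_dataset(rng)
        rep = mimic_stress_test(lambda X: np.zeros(len(X)), ds)
        assert rep.overall_count == 0
        assert rep.overall_rate == 0.0

    def test_always_positive_full_fpr(self, rng):
        ds = _mimic_dataset(rng)
        rep = mimic_stress_test(lambda X: np.ones(len(X)), ds)
        assert all(r == 1.0 for r in rep.rates.values())
        assert rep.overall_n == 14

    def test_category_counts_sum_to_overall(self, rng):
        ds = _mimic_dataset(rng)
        rng2 = np.random.default_rng(0)
        rep = mimic_stress_test(lambda X: rng2.uniform(size=len(X)), ds)
        assert rep.overall_count == sum(rep.counts.values())

    def test_brugada_contamination_rejected(self, rng):
        ds = _mimic_dataset(rng)
        ds.labels[0] = "brugada_type1"
        with pytest.raises(ValueError):
            mimic_stress_test(lambda X: np.zeros(len(X)), ds)


class TestLearningCurve:
    def test_table_shape_and_reproducibility(self):
        calls = []

        def runner(frac, seed):
            calls.append((frac, seed))
            return dict(auc=frac + seed * 1e-6)

        table = learning_curve(runner, pd.DataFrame(), [0.25, 0.8],
                               n_seeds=3, base_seed=10)
        assert len(table) == 2
        assert list(table["train_fraction"]) == [0.25, 0.8]
        assert len(calls) == 6

    def test_nonincreasing_fractions_rejected(self):
        with pytest.raises(ValueError):
            learning_curve(lambda f, s: {}, pd.DataFrame(), [0.8, 0.25], 1)
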