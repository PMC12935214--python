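"""Evaluation metrics and paired model-comparison statistics.

Implements the nine-metric report (accuracy, F1, AUC, sensitivity,
specificity, NPV, PPV, average precision, Brier), the DeLong test for
correlated AUCs, McNemar's test at a fixed threshold, Holm step-down
multiplicity adjustment, the paired bootstrap over test-set beats,
cross-validation summaries, the Brugada-mimic false-positive report and a
learning-curve harness.  The evaluation unit is the beat; the mimic report
aggregates to records by majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

from .containers import BRUGADA_CLASSES, MIMIC_CLASSES, BeatDataset

METRIC_NAMES = ("accuracy", "f1", "auc", "sensitivity", "specificity",
                "npv", "ppv", "average_precision", "brier")


class SingleClassError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Metric report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    accuracy: float
    f1: float
    auc: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    average_precision: float
    brier: float
    n: int
    threshold: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES} | {
            "n": self.n, "threshold": self.threshold}


def _check_binary(y_true: np.ndarray) -> np.ndarray:
    y = np.asarray(y_true).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y_true must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise SingleClassError("AUC undefined: y_true contains a single class")
    return y


def compute_metrics(y_true, y_score, threshold: float = 0.5) -> MetricReport:
    y = _check_binary(y_true)
    s = np.asarray(y_score, dtype=np.float64)
    if s.shape != y.shape:
        raise ValueError("y_true and y_score lengths differ")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)

    def _safe(a, b):
        return a / b if b else float("nan")

    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    ppv = _safe(tp, tp + fp)
    npv = _safe(tn, tn + fn)
    f1 = _safe(2 * tp, 2 * tp + fp + fn)
    return MetricReport(
        accuracy=(tp + tn) / n,
        f1=f1,
        auc=float(roc_auc_score(y, s)),
        sensitivity=sens,
        specificity=spec,
        npv=npv,
        ppv=ppv,
        average_precision=float(average_precision_score(y, s)),
        brier=float(np.mean((s - y) ** 2)),
        n=n,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, score: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its structural components V10 (per positive), V01 (per negative)."""
    pos = score[y == 1]
    neg = score[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def delong_auc_variance(y_true, y_score) -> tuple[float, float]:
    """(AUC, DeLong variance) for one model."""
    y = _check_binary(y_true)
    auc, v10, v01 = _delong_components(y, np.asarray(y_score, dtype=np.float64))
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return auc, float(var)


def delong_test(y_true, score_a, score_b) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two correlated AUCs.

    Returns (auc_a, auc_b, z, two-sided p)."""
    y = _check_binary(y_true)
    sa = np.asarray(score_a, dtype=np.float64)
    sb = np.asarray(score_b, dtype=np.float64)
    auc_a, v10a, v01a = _delong_components(y, sa)
    auc_b, v10b, v01b = _delong_components(y, sb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n  # 2x2 covariance of (auc_a, auc_b)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# McNemar test
# ---------------------------------------------------------------------------

def mcnemar_test(y_true, pred_a, pred_b, exact_limit: int = 25
                 ) -> tuple[int, int, float]:
    """Paired McNemar test on discordant counts.

    b = samples model A classifies correctly and B misclassifies; c = the
    converse.  Exact binomial two-sided p for b + c < ``exact_limit``,
    chi-square with continuity correction otherwise.  Returns (b, c, p)."""
    y = np.asarray(y_true).astype(int)
    a_ok = np.asarray(pred_a).astype(int) == y
    b_ok = np.asarray(pred_b).astype(int) == y
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return b, c, 1.0
    table = [[0, b], [c, 0]]
    exact = (b + c) < exact_limit
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return b, c, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Holm step-down
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Paired bootstrap
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    table: pd.DataFrame = field(repr=False)  # one row per metric
    n_resamples: int = 0
    delong: tuple | None = None
    mcnemar: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.table.assign(model_a=self.model_a, model_b=self.model_b)


def _fast_auc(y: np.ndarray, s: np.ndarray) -> float:
    r = stats.rankdata(s)
    m = int(y.sum())
    n = len(y) - m
    return (r[y == 1].sum() - m * (m + 1) / 2) / (m * n)


def _all_metrics_fast(y: np.ndarray, s: np.ndarray, thr: float,
                      need: frozenset = frozenset(METRIC_NAMES)) -> np.ndarray:
    pred = s >= thr
    tp = np.sum(pred & (y == 1)); tn = np.sum(~pred & (y == 0))
    fp = np.sum(pred & (y == 0)); fn = np.sum(~pred & (y == 1))
    n = len(y)
    nan = float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = [
            (tp + tn) / n,
            2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else nan,
            _fast_auc(y, s) if "auc" in need else nan,
            tp / (tp + fn) if (tp + fn) else nan,
            tn / (tn + fp) if (tn + fp) else nan,
            tn / (tn + fn) if (tn + fn) else nan,
            tp / (tp + fp) if (tp + fp) else nan,
            float(average_precision_score(y, s))
            if "average_precision" in need else nan,
            float(np.mean((s - y) ** 2)),
        ]
    return np.array(vals)


def paired_bootstrap(y_true, score_a, score_b, n_resamples: int = 1000,
                     seed: int = 42, threshold: float = 0.5,
                     model_ids: tuple[str, str] = ("A", "B"),
                     metrics: tuple[str, ...] = METRIC_NAMES
                     ) -> ComparisonResult:
    """Beat-level paired bootstrap: identical index resamples applied to the
    truth vector and both score vectors; every metric recomputed per
    replicate.  Reports mean difference (A - B), percentile 95% CI and the
    empirical two-sided p per metric."""
    import warnings
    if n_resamples < 100:
        warnings.warn(f"n_resamples={n_resamples} is small; interval "
                      "estimates will be unstable", stacklevel=2)
    y = _check_binary(y_true)
    sa = np.asarray(score_a, dtype=np.float64)
    sb = np.asarray(score_b, dtype=np.float64)
    rng = np.random.default_rng(seed)
    cols = [METRIC_NAMES.index(m) for m in metrics]
    need = frozenset(metrics)

    diffs = np.empty((n_resamples, len(cols)))
    i = 0
    while i < n_resamples:
        idx = rng.integers(0, len(y), size=len(y))
        yi = y[idx]
        if yi.min() == yi.max():  # degenerate resample: redraw
            continue
        da = _all_metrics_fast(yi, sa[idx], threshold, need)[cols]
        db = _all_metrics_fast(yi, sb[idx], threshold, need)[cols]
        diffs[i] = da - db
        i += 1

    mean = diffs.mean(axis=0)
    lo, hi = np.percentile(diffs, [2.5, 97.5], axis=0)
    p_emp = np.minimum(1.0, 2 * np.minimum(
        (1 + (diffs <= 0).sum(axis=0)) / (n_resamples + 1),
        (1 + (diffs >= 0).sum(axis=0)) / (n_resamples + 1)))
    table = pd.DataFrame(dict(metric=list(metrics), mean_diff=mean,
                              ci_low=lo, ci_high=hi, p_boot=p_emp))
    pa = (sa >= threshold).astype(int)
    pb = (sb >= threshold).astype(int)
    return ComparisonResult(model_ids[0], model_ids[1], table, n_resamples,
                            delong=delong_test(y, sa, sb),
                            mcnemar=mcnemar_test(y, pa, pb))


# ---------------------------------------------------------------------------
# Cross-validation summary
# ---------------------------------------------------------------------------

def summarise_cv(fold_reports: list[MetricReport]) -> pd.DataFrame:
    """Mean +/- sd and 95% t-interval over fold means, per metric."""
    k = len(fold_reports)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rows = []
    tcrit = stats.t.ppf(0.975, df=k - 1)
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in fold_reports], dtype=np.float64)
        mean, sd = vals.mean(), vals.std(ddof=1)
        half = tcrit * sd / np.sqrt(k)
        rows.append(dict(metric=m, mean=mean, sd=sd,
                         ci_low=mean - half, ci_high=mean + half))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mimic stress test
# ---------------------------------------------------------------------------

@dataclass
class MimicReport:
    counts: dict[str, int]
    totals: dict[str, int]
    rates: dict[str, float]
    overall_count: int
    overall_n: int
    overall_rate: float

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(category=c, n=self.totals[c], false_positives=self.counts[c],
                     rate=self.rates[c]) for c in self.counts]
        rows.append(dict(category="overall", n=self.overall_n,
                         false_positives=self.overall_count,
                         rate=self.overall_rate))
        return pd.DataFrame(rows)


def mimic_stress_test(predict_proba, mimic_beats: BeatDataset,
                      threshold: float = 0.5) -> MimicReport:
    """False-positive rates of a Brugada classifier on a mimic-only cohort.

    ``predict_proba(beats) -> positive-class probability per beat``.  A record
    counts as a false positive when the majority of its beats score positive.
    """
    labels = set(mimic_beats.labels)
    if labels & BRUGADA_CLASSES:
        raise ValueError("mimic cohort must not contain Brugada-pattern records")
    scores = np.asarray(predict_proba(mimic_beats.beats), dtype=np.float64)
    pos = scores >= threshold

    counts = {c: 0 for c in MIMIC_CLASSES if c in labels}
    totals = {c: 0 for c in counts}
    for rid in pd.unique(mimic_beats.record_ids):
        mask = mimic_beats.record_ids == rid
        cat = mimic_beats.labels[mask][0]
        if cat not in counts:
            continue
        totals[cat] += 1
        if pos[mask].mean() > 0.5:
            counts[cat] += 1
    rates = {c: counts[c] / totals[c] if totals[c] else float("nan")
             for c in counts}
    overall_count = sum(counts.values())
    overall_n = sum(totals.values())
    return MimicReport(counts, totals, rates, overall_count, overall_n,
                       overall_count / overall_n if overall_n else float("nan"))


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------

def learning_curve(strategy_runner, manifest: pd.DataFrame,
                   train_fractions: list[float], n_seeds: int,
                   base_seed: int = 42) -> pd.DataFrame:
    """Median metrics versus labelled training-set size.

    ``strategy_runner(train_fraction, seed) -> dict of metrics`` must train
    on a patient subsample of the stated fraction and evaluate on the fixed
    test set.  Fractions must be increasing and feasible."""
    fr = list(train_fractions)
    if fr != sorted(fr):
        raise ValueError("train_fractions must be increasing")
    if any(not 0 < f < 1 for f in fr):
        raise ValueError("fractions must lie in (0, 1)")
    rows = []
    for frac in fr:
        per_seed = [strategy_runner(frac, base_seed + s) for s in range(n_seeds)]
        keys = per_seed[0].keys()
        med = {k: float(np.median([d[k] for d in per_seed])) for k in keys}
        rows.append(dict(train_fraction=frac, n_seeds=n_seeds, **med))
    return pd.DataFrame(rows)
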