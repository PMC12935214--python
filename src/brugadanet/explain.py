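"""Gradient-based attributions and explainability sanity checks.

Attribution estimator: expected gradients — for sample x, background draw b
and interpolation coefficient a ~ U(0,1), average (x - b) * grad_x f(b + a(x-b))
over draws, where f is the positive-class logit.  This is a Shapley-style
path attribution relative to a background reference distribution, computed
with the package's own autograd (input gradients through the frozen-statistics
batch-norm evaluation mode).

Sanity machinery: per-lead importance summaries, the top-down parameter
randomisation cascade (attribution similarity should decay toward chance as
trained weights are destroyed), and lead ablation (probability drop when
zero-masking leads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .backbone import ModelBundle, build_backbone, attach_head
from .containers import LEADS, BeatDataset
from .evalstats import _fast_auc
from .preprocess import LeakageError


@dataclass
class AttributionMap:
    values: np.ndarray  # (n_samples, 12, W)
    seed: int
    n_draws: int
    background_n: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution values must be finite")


@dataclass
class SanityCurve:
    stages: list[str]
    spearman: list[float]
    auc: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = dict(stage=self.stages, spearman=self.spearman)
        if self.auc:
            d["auc"] = self.auc
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Expected gradients
# ---------------------------------------------------------------------------

def _positive_logit(bundle: ModelBundle, x: nn.Tensor) -> nn.Tensor:
    out = bundle.forward(None, input_tensor=x)
    if bundle.head_kind == "binary":
        return out
    raise ValueError("attributions are defined for the binary head")


def gradient_attributions(bundle: ModelBundle, background: np.ndarray,
                          samples: np.ndarray, n_draws: int = 100,
                          seed: int = 42,
                          background_dataset: BeatDataset | None = None,
                          train_patients: frozenset[str] | None = None
                          ) -> AttributionMap:
    """Expected-gradients attribution toward the positive (Brugada) class.

    If ``background_dataset``/``train_patients`` are supplied, the background
    is checked to come from the training partition only and to contain no
    SMOTE-synthetic beats.
    """
    if background_dataset is not None:
        if background_dataset.synthetic.any():
            raise LeakageError("background must exclude synthetic beats")
        if train_patients is not None and not (
                set(background_dataset.patient_ids) <= set(train_patients)):
            raise LeakageError("background beats must come from the training "
                               "partition")
    bg = np.asarray(background, dtype=np.float32)
    xs = np.asarray(samples, dtype=np.float32)
    if xs.ndim == 2:
        xs = xs[None]
    rng = np.random.default_rng(seed)
    bundle.train(False)

    maps = np.empty_like(xs, dtype=np.float64)
    for i, x in enumerate(xs):
        bidx = rng.integers(0, len(bg), size=n_draws)
        alpha = rng.uniform(0.0, 1.0, size=n_draws).astype(np.float32)
        b = bg[bidx]
        interp = b + alpha[:, None, None] * (x[None] - b)
        xt = nn.Tensor(interp, requires_grad=True)
        logit = _positive_logit(bundle, xt)
        # summing the batch of independent logits yields per-row input grads
        total = logit.mean() * float(logit.data.size)
        total.backward()
        maps[i] = np.mean((x[None] - b) * xt.grad, axis=0)
    return AttributionMap(maps, seed=seed, n_draws=n_draws, background_n=len(bg))


# ---------------------------------------------------------------------------
# Lead-level summaries
# ---------------------------------------------------------------------------

def lead_importance(maps: AttributionMap) -> pd.DataFrame:
    """Per-lead mean |attribution| (+/- sd over samples) and top-3 frequency."""
    a = np.abs(maps.values)  # (n, 12, W)
    if a.shape[0] < 1:
        raise ValueError("need at least one attribution map")
    per_sample_lead = a.mean(axis=2)  # (n, 12)
    mean = per_sample_lead.mean(axis=0)
    sd = per_sample_lead.std(axis=0, ddof=0)
    # per-sample lead ranking by summed |attribution|; ties straddling the
    # rank-3 boundary share the remaining top-3 credit equally
    sums = a.sum(axis=2)
    credit = np.zeros(len(LEADS))
    for row in sums:
        order = np.sort(row)[::-1]
        thr = order[2]
        above = row > thr
        tied = row == thr
        credit[above] += 1.0
        credit[tied] += (3 - above.sum()) / tied.sum()
    freq = credit / a.shape[0]
    return pd.DataFrame(dict(lead=list(LEADS), mean_abs_attr=mean, sd=sd,
                             top3_frequency=freq))


# ---------------------------------------------------------------------------
# Parameter-randomisation sanity check
# ---------------------------------------------------------------------------

def _reinit_group(bundle: ModelBundle, group: str, rng: np.random.Generator) -> None:
    for p in bundle.parameters():
        if p.block != group:
            continue
        if p.name.endswith(".b") or p.name == "bn.beta":
            p.data = np.zeros_like(p.data)
        elif p.name == "bn.gamma":
            p.data = np.ones_like(p.data)
        else:  # He-style fresh draw for weight matrices/kernels
            fan_in = int(np.prod(p.data.shape[1:])) or p.data.shape[0]
            p.data = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                size=p.data.shape).astype(np.float32)


def randomisation_sanity_check(bundle: ModelBundle, samples: np.ndarray,
                               background: np.ndarray, seed: int = 42,
                               n_draws: int = 32,
                               y_true: np.ndarray | None = None) -> SanityCurve:
    """Top-down cascading re-initialisation with attribution similarity.

    Stage 0 ("none") is the trained model (Spearman rho 1 by definition);
    then the head, then each dense block from the top down are cumulatively
    re-initialised.  At each stage attributions are recomputed and the mean
    per-sample Spearman correlation of flattened |maps| against the trained
    reference is recorded, together with the stage AUC when labels are given.
    """
    from .strategies import _copy_bundle

    n_blocks = bundle.backbone.cfg.n_dense_blocks
    stages = ["none", "head"] + [f"block{i}" for i in range(n_blocks, 0, -1)]
    rng = np.random.default_rng(seed)

    ref = gradient_attributions(bundle, background, samples,
                                n_draws=n_draws, seed=seed)
    ref_flat = np.abs(ref.values).reshape(len(ref.values), -1)

    work = _copy_bundle(bundle)
    rhos, aucs = [], []
    for stage in stages:
        if stage == "head":
            _reinit_group(work, "head", rng)
        elif stage.startswith("block"):
            _reinit_group(work, stage, rng)
        if stage == "none":
            rhos.append(1.0)
            cur = ref
        else:
            cur = gradient_attributions(work, background, samples,
                                        n_draws=n_draws, seed=seed)
            cur_flat = np.abs(cur.values).reshape(len(cur.values), -1)
            per_sample = [stats.spearmanr(a, b).statistic
                          for a, b in zip(ref_flat, cur_flat)]
            rhos.append(float(np.nanmean(per_sample)))
        if y_true is not None:
            scores = work.predict_proba(samples) if stage != "none" \
                else bundle.predict_proba(samples)
            aucs.append(float(_fast_auc(np.asarray(y_true).astype(int), scores)))
    return SanityCurve(stages, rhos, aucs)


# ---------------------------------------------------------------------------
# Lead ablation
# ---------------------------------------------------------------------------

def lead_ablation(bundle: ModelBundle, beats: np.ndarray,
                  lead_subsets: list[tuple[str, ...]],
                  mask_value: float | str = 0.0,
                  reference_beats: np.ndarray | None = None) -> pd.DataFrame:
    """Mean drop in predicted positive-class probability when masking leads.

    ``mask_value`` is either a constant (default 0, the normalised
    isoelectric level) or ``"mean"``, which imputes the population-average
    trace of each masked lead.  The average is taken over
    ``reference_beats`` when given (use a class-mixed set so the imputed
    trace carries no class evidence), otherwise over ``beats``.  Mean
    imputation keeps masked inputs on the data manifold, so deltas isolate
    the class evidence a lead carries rather than the shock of an all-zero
    channel.  delta = mean over beats of
    P(positive | original) - P(positive | masked).
    """
    X = np.asarray(beats, dtype=np.float32)
    base = bundle.predict_proba(X)
    ref = X if reference_beats is None else np.asarray(reference_beats,
                                                      dtype=np.float32)
    lead_means = ref.mean(axis=0)  # (12, W) population-average traces
    rows = []
    for subset in lead_subsets:
        if len(subset) == len(LEADS):
            warnings.warn("masking all 12 leads is degenerate", stacklevel=2)
        Xm = X.copy()
        for lead in subset:
            i = LEADS.index(lead)
            Xm[:, i, :] = lead_means[i] if mask_value == "mean" else mask_value
        masked = bundle.predict_proba(Xm) if subset else base
        rows.append(dict(leads="+".join(subset) if subset else "(none)",
                         delta=float(np.mean(base - masked))))
    return pd.DataFrame(rows)
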