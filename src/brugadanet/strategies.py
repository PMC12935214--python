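"""Training regimes for the scarce-data comparison.

Three families are implemented over the shared DenseNet backbone:

* ``baseline`` — supervised training of the full network on the scarce
  labelled training split (also the degenerate case of fine-tuning with a
  random initialisation and nothing frozen);
* supervised pretraining — train f(.) on a large labelled cohort
  (RBBB-vs-normal binary, or a five-class task), transfer the weights and
  fine-tune with all but the final two dense blocks frozen;
* self-supervised contrastive pretraining — SimCLR (in-batch negatives)
  or MoCo-V2 (momentum key encoder + FIFO negative queue), with stochastic
  baseline-drift and Gaussian-noise views of each beat.  Augmentations are
  used only here, never during supervised fine-tuning.

All loops are seed-deterministic; every entry point requires a seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .backbone import (BackboneConfig, ModelBundle, attach_head, build_backbone,
                       freeze_for_finetune, load_checkpoint, save_checkpoint)
from .containers import BeatDataset


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationParams:
    #: drift amplitude in normalised signal units
    drift_amplitude_range: tuple[float, float] = (0.02, 0.10)
    #: drift frequency in cycles per beat window (respiration-like, slow)
    drift_frequency_range: tuple[float, float] = (0.05, 0.5)
    noise_sd_range: tuple[float, float] = (0.005, 0.04)
    enabled_ops: tuple[str, ...] = ("baseline_drift", "gaussian_noise")
    #: one shared drift trace for all 12 leads (respiration is coherent)
    drift_shared_across_leads: bool = True

    def __post_init__(self) -> None:
        for rng_ in (self.drift_amplitude_range, self.drift_frequency_range,
                     self.noise_sd_range):
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid range {rng_}")
        for op in self.enabled_ops:
            if op not in ("baseline_drift", "gaussian_noise"):
                raise ValueError(f"unknown augmentation {op!r}")


def augment_baseline_drift(beat: np.ndarray, params: AugmentationParams,
                           rng: np.random.Generator) -> np.ndarray:
    """Add a random low-frequency sinusoidal offset (respiratory drift)."""
    _, W = beat.shape
    amp = rng.uniform(*params.drift_amplitude_range)
    freq = rng.uniform(*params.drift_frequency_range)
    if amp == 0.0:
        return beat.copy()
    t = np.arange(W) / W
    if params.drift_shared_across_leads:
        drift = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        return beat + drift[None, :]
    phases = rng.uniform(0, 2 * np.pi, size=beat.shape[0])
    return beat + amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])


def augment_gaussian_noise(beat: np.ndarray, params: AugmentationParams,
                           rng: np.random.Generator) -> np.ndarray:
    """Superimpose i.i.d. zero-mean Gaussian noise (fibrillation-wave-like)."""
    sd = rng.uniform(*params.noise_sd_range)
    if sd == 0.0:
        return beat.copy()
    return beat + rng.normal(0.0, sd, size=beat.shape)


_AUG_OPS = {"baseline_drift": augment_baseline_drift,
            "gaussian_noise": augment_gaussian_noise}


def augment_view(beat: np.ndarray, params: AugmentationParams,
                 rng: np.random.Generator) -> np.ndarray:
    out = beat
    for op in params.enabled_ops:
        out = _AUG_OPS[op](out, params, rng)
    return out if out is not beat else beat.copy()


# ---------------------------------------------------------------------------
# Contrastive loss
# ---------------------------------------------------------------------------

def nt_xent_loss(embeddings: nn.Tensor, temperature: float = 0.5) -> nn.Tensor:
    """Normalised-temperature cross-entropy over cosine similarities.

    Rows are ordered [view-A of items 1..N, view-B of items 1..N]; row i's
    positive is row (i+N) mod 2N, all other rows are negatives.  Symmetric in
    pair order by construction (both directions appear as anchors).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    two_n = embeddings.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("need an even number (2N) of embedding rows")
    n = two_n // 2
    z = nn.normalize_rows(embeddings)
    sims = nn.matmul(z, nn.transpose(z)) * (1.0 / temperature)
    mask = nn.Tensor(np.where(np.eye(two_n, dtype=bool), -1e9, 0.0))
    targets = np.concatenate([np.arange(n, two_n), np.arange(0, n)])
    return nn.softmax_cross_entropy(sims + mask, targets)


# ---------------------------------------------------------------------------
# Configs and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastiveConfig:
    framework: str = "simclr"  # or "moco_v2"
    temperature: float = 0.5
    batch_size: int = 64
    queue_size: int = 1024
    momentum: float = 0.999
    epochs: int = 10
    learning_rate: float = 1e-3
    projection_dim: int = 32
    seed: int = 42

    def __post_init__(self) -> None:
        if self.framework not in ("simclr", "moco_v2"):
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 2:
            raise ValueError("contrastive training needs batch_size >= 2 "
                             "(no negatives otherwise)")
        if self.framework == "moco_v2":
            if self.queue_size <= 0:
                raise ValueError("queue_size must be positive")
            if not 0.0 <= self.momentum <= 1.0:
                raise ValueError("momentum must lie in [0, 1]")
            if self.queue_size % self.batch_size:
                raise ValueError("queue_size must be a multiple of batch_size")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 10  # early-stopping patience on validation loss
    seed: int = 42


@dataclass
class TrainReport:
    strategy: str
    pretrain_dataset: str | None
    loss_curve: list[float]
    epochs_run: int
    checkpoint: str | None
    wall_time_s: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Shared loop helpers
# ---------------------------------------------------------------------------

def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        idx = order[i : i + batch_size]
        if len(idx) >= 2:  # batch norm needs >1 sample
            yield idx


def _copy_bundle(src: ModelBundle) -> ModelBundle:
    dst = build_backbone(src.backbone.cfg, seed=0)
    if src.head is not None:
        dst = attach_head(dst, src.head_kind,
                          src.head.parameters()[-1].data.shape[-1], seed=0)
    for ps, pd_ in zip(src.parameters(), dst.parameters()):
        pd_.data = ps.data.copy()
    for bs, bd in zip(src.backbone.batchnorms(), dst.backbone.batchnorms()):
        bd.running_mean = bs.running_mean.copy()
        bd.running_var = bs.running_var.copy()
    return dst


def momentum_update(key: ModelBundle, query: ModelBundle, m: float) -> None:
    """theta_k <- m * theta_k + (1 - m) * theta_q (incl. batch-norm stats)."""
    for pk, pq in zip(key.parameters(), query.parameters()):
        pk.data = m * pk.data + (1.0 - m) * pq.data
    for bk, bq in zip(key.backbone.batchnorms(), query.backbone.batchnorms()):
        bk.running_mean = m * bk.running_mean + (1.0 - m) * bq.running_mean
        bk.running_var = m * bk.running_var + (1.0 - m) * bq.running_var


# ---------------------------------------------------------------------------
# Supervised pretraining
# ---------------------------------------------------------------------------

PRETRAIN_TASKS = {"rbbb_vs_normal": 2, "five_class": 5}


def pretrain_supervised(beats: np.ndarray, labels: np.ndarray, task: str,
                        backbone_config: BackboneConfig, seed: int,
                        train_config: TrainConfig | None = None,
                        checkpoint_path=None) -> tuple[TrainReport, ModelBundle]:
    """Cross-entropy pretraining of f(.) + classifier head on a large
    labelled cohort; the checkpoint exports f(.) only."""
    if task not in PRETRAIN_TASKS:
        raise ValueError(f"unknown pretraining task {task!r}")
    tc = train_config or TrainConfig(seed=seed)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("pretraining needs at least two classes")
    y = np.searchsorted(classes, labels).astype(np.int64)
    n_out = 1 if task == "rbbb_vs_normal" else PRETRAIN_TASKS[task]

    bundle = build_backbone(backbone_config, seed=seed)
    attach_head(bundle, "binary" if n_out == 1 else "kclass", n_out, seed=seed + 1)
    bundle.train(True)
    opt = nn.Adam(bundle.trainable_parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(seed)
    X = np.asarray(beats, dtype=np.float32)

    t0 = time.perf_counter()
    curve = []
    for _ in range(tc.epochs):
        losses = []
        for idx in _iterate_batches(len(X), tc.batch_size, rng):
            opt.zero_grad()
            logits = bundle.forward(X[idx])
            if n_out == 1:
                loss = nn.sigmoid_bce_with_logits(logits, y[idx])
            else:
                loss = nn.softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
    path = None
    if checkpoint_path is not None:
        path = str(save_checkpoint(bundle, checkpoint_path, include_head=False))
    report = TrainReport("supervised", task, curve, len(curve), path,
                         time.perf_counter() - t0)
    return report, bundle


# ---------------------------------------------------------------------------
# Contrastive pretraining
# ---------------------------------------------------------------------------

def _two_views(X: np.ndarray, idx: np.ndarray, aug: AugmentationParams,
               rng: np.random.Generator) -> np.ndarray:
    va = np.stack([augment_view(X[i], aug, rng) for i in idx])
    vb = np.stack([augment_view(X[i], aug, rng) for i in idx])
    return np.concatenate([va, vb]).astype(np.float32)


def pretrain_simclr(unlabelled_beats: np.ndarray, config: ContrastiveConfig,
                    aug: AugmentationParams, backbone_config: BackboneConfig,
                    checkpoint_path=None) -> tuple[TrainReport, ModelBundle]:
    """SimCLR pretraining: two stochastic views per beat, NT-Xent over the
    batch; the projection head is discarded at checkpoint export."""
    X = np.asarray(unlabelled_beats, dtype=np.float32)
    if len(X) == 0:
        raise ValueError("empty unlabelled beat set")
    bundle = build_backbone(backbone_config, seed=config.seed)
    attach_head(bundle, "projection", config.projection_dim, seed=config.seed + 1)
    bundle.train(True)
    opt = nn.Adam(bundle.trainable_parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    t0 = time.perf_counter()
    curve = []
    for _ in range(config.epochs):
        losses = []
        for idx in _iterate_batches(len(X), config.batch_size, rng):
            opt.zero_grad()
            views = _two_views(X, idx, aug, rng)
            loss = nt_xent_loss(bundle.forward(views), config.temperature)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
    path = None
    if checkpoint_path is not None:
        path = str(save_checkpoint(bundle, checkpoint_path, include_head=False))
    report = TrainReport("simclr", None, curve, len(curve), path,
                         time.perf_counter() - t0)
    return report, bundle


def pretrain_moco_v2(unlabelled_beats: np.ndarray, config: ContrastiveConfig,
                     aug: AugmentationParams, backbone_config: BackboneConfig,
                     checkpoint_path=None) -> tuple[TrainReport, ModelBundle]:
    """MoCo-V2 pretraining: a momentum-updated key encoder fills a FIFO queue
    of negative embeddings; the query encoder trains against queue negatives."""
    X = np.asarray(unlabelled_beats, dtype=np.float32)
    if len(X) == 0:
        raise ValueError("empty unlabelled beat set")
    query = build_backbone(backbone_config, seed=config.seed)
    attach_head(query, "projection", config.projection_dim, seed=config.seed + 1)
    query.train(True)
    key = _copy_bundle(query)
    key.train(True)
    for p in key.parameters():
        p.requires_grad = False

    opt = nn.Adam(query.trainable_parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    queue = np.zeros((config.queue_size, config.projection_dim), dtype=np.float32)
    queue_len = 0
    queue_ptr = 0
    queue_history: list[int] = []

    t0 = time.perf_counter()
    curve = []
    for _ in range(config.epochs):
        losses = []
        for idx in _iterate_batches(len(X), config.batch_size, rng):
            opt.zero_grad()
            va = np.stack([augment_view(X[i], aug, rng) for i in idx]).astype(np.float32)
            vb = np.stack([augment_view(X[i], aug, rng) for i in idx]).astype(np.float32)
            q = nn.normalize_rows(query.forward(va))
            with_keys = key.forward(vb).data
            k = with_keys / np.linalg.norm(with_keys, axis=1, keepdims=True)

            pos = nn.matmul(q * nn.Tensor(k), nn.Tensor(np.ones((config.projection_dim, 1))))
            logits_list = [pos]
            if queue_len > 0:
                logits_list.append(nn.matmul(q, nn.Tensor(queue[:queue_len].T)))
            logits = nn.concat(logits_list, axis=1) * (1.0 / config.temperature)
            loss = nn.softmax_cross_entropy(logits, np.zeros(len(idx), dtype=np.int64))
            loss.backward()
            opt.step()
            momentum_update(key, query, config.momentum)

            # FIFO enqueue of this step's keys
            b = len(idx)
            for row in k:
                queue[queue_ptr] = row
                queue_ptr = (queue_ptr + 1) % config.queue_size
            queue_len = min(queue_len + b, config.queue_size)
            queue_history.append(queue_len)
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
    path = None
    if checkpoint_path is not None:
        path = str(save_checkpoint(query, checkpoint_path, include_head=False))
    report = TrainReport("moco_v2", None, curve, len(curve), path,
                         time.perf_counter() - t0,
                         extras=dict(queue_length_history=queue_history))
    return report, query


# ---------------------------------------------------------------------------
# Fine-tuning / baseline
# ---------------------------------------------------------------------------

def finetune(checkpoint, train_set: BeatDataset, val_set: BeatDataset,
             backbone_config: BackboneConfig, seed: int,
             freeze_final_blocks: int | None = 2,
             train_config: TrainConfig | None = None
             ) -> tuple[TrainReport, ModelBundle]:
    """Train the binary Brugada classifier.

    ``checkpoint=None`` with ``freeze_final_blocks=None`` is the baseline
    strategy (random initialisation, fully trainable).  With a checkpoint the
    transferred extractor is frozen except for the final ``freeze_final_blocks``
    dense blocks.  Early stopping monitors validation loss.
    """
    tc = train_config or TrainConfig(seed=seed)
    if checkpoint is not None:
        bundle = load_checkpoint(checkpoint, backbone_config)
        strategy = "finetune"
    else:
        bundle = build_backbone(backbone_config, seed=seed)
        strategy = "baseline"
    attach_head(bundle, "binary", 1, seed=seed + 1)
    if checkpoint is not None and freeze_final_blocks is not None:
        freeze_for_finetune(bundle, freeze_final_blocks)

    Xtr = train_set.beats.astype(np.float32)
    ytr = train_set.binary_targets()
    Xva = val_set.beats.astype(np.float32)
    yva = val_set.binary_targets()
    if len(np.unique(ytr)) < 2:
        raise ValueError("training partition must contain both classes")

    opt = nn.Adam(bundle.trainable_parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(seed)
    best_val = np.inf
    best_params = None
    best_epoch = 0
    curve = []
    t0 = time.perf_counter()
    for epoch in range(tc.epochs):
        bundle.train(True)
        losses = []
        for idx in _iterate_batches(len(Xtr), tc.batch_size, rng):
            opt.zero_grad()
            loss = nn.sigmoid_bce_with_logits(bundle.forward(Xtr[idx]), ytr[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))

        bundle.train(False)
        val_logits = bundle.forward(Xva)
        val_loss = float(nn.sigmoid_bce_with_logits(val_logits, yva).data)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_epoch = epoch
            best_params = [p.data.copy() for p in bundle.parameters()]
        elif epoch - best_epoch >= tc.patience:
            break
    if best_params is not None:
        for p, d in zip(bundle.parameters(), best_params):
            p.data = d
    bundle.train(False)
    report = TrainReport(strategy, None, curve, len(curve), None,
                         time.perf_counter() - t0,
                         extras=dict(best_val_loss=best_val, best_epoch=best_epoch))
    return report, bundle


# ---------------------------------------------------------------------------
# Augmentation ablation harness
# ---------------------------------------------------------------------------

def augmentation_ablation(framework: str, unlabelled_beats: np.ndarray,
                          augmentations: dict[str, AugmentationParams],
                          downstream_eval, config: ContrastiveConfig,
                          backbone_config: BackboneConfig,
                          include_combined: bool = True) -> pd.DataFrame:
    """Pretrain once per augmentation setting (identical pipeline otherwise)
    and score each checkpoint with ``downstream_eval(bundle) -> dict``."""
    if not augmentations:
        raise ValueError("need at least one augmentation setting")
    settings = dict(augmentations)
    if include_combined and len(augmentations) > 1:
        ops = tuple(op for a in augmentations.values() for op in a.enabled_ops)
        base = next(iter(augmentations.values()))
        settings["combined"] = AugmentationParams(
            drift_amplitude_range=base.drift_amplitude_range,
            drift_frequency_range=base.drift_frequency_range,
            noise_sd_range=base.noise_sd_range,
            enabled_ops=tuple(dict.fromkeys(ops)))
    pretrain = pretrain_simclr if framework == "simclr" else pretrain_moco_v2
    rows = []
    for name, aug in settings.items():
        if _is_identity(aug):
            warnings.warn(f"augmentation setting {name!r} is the identity: "
                          "the contrastive task is degenerate (representation "
                          "collapse likely)", stacklevel=2)
        _, bundle = pretrain(unlabelled_beats, config, aug, backbone_config)
        rows.append(dict(augmentation=name, framework=framework,
                         **downstream_eval(bundle)))
    return pd.DataFrame(rows)


def _is_identity(aug: AugmentationParams) -> bool:
    if not aug.enabled_ops:
        return True
    checks = {"baseline_drift": aug.drift_amplitude_range[1] == 0.0,
              "gaussian_noise": aug.noise_sd_range[1] == 0.0}
    return all(checks[op] for op in aug.enabled_ops)
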