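"""1D convolutional DenseNet feature extractor with attachable heads.

The feature extractor f(.) is a stem convolution followed by
``n_dense_blocks`` dense blocks.  Within a block every layer receives the
concatenation of the block input and all previous layer outputs; a 1x1
transition convolution then compresses back to a fixed trunk width and the
time axis is average-pooled (stride 2) while it remains long enough.  Global
average pooling plus a linear map yields a fixed-length embedding, so the
embedding dimension is independent of the input window length.

Heads: a classifier (single linear layer; 1 logit for binary, k logits for
k-class) or a two-layer ReLU projection head g(.) for contrastive
pretraining.  Each parameter carries a freeze-group label ("block1" ..
"blockN", or "head"); the stem freezes with block 1 and the embedding
projection with block N, so the per-block trainable mask of transfer
learning has exactly ``n_dense_blocks`` entries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn


class ConfigurationError(ValueError):
    pass


class TransferError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    n_dense_blocks: int = 10
    layers_per_block: int = 2
    growth_rate: int = 16
    kernel_size: int = 7
    input_shape: tuple[int, int] = (12, 100)
    embedding_dim: int = 64
    trunk_channels: int = 24
    min_pool_length: int = 8

    def __post_init__(self) -> None:
        if self.n_dense_blocks < 2:
            raise ConfigurationError("need >= 2 dense blocks (final two must be "
                                     "independently freezable)")
        if self.layers_per_block < 1 or self.growth_rate < 1:
            raise ConfigurationError("invalid block internals")
        if len(self.input_shape) != 2 or min(self.input_shape) < 1:
            raise ConfigurationError(f"invalid input shape {self.input_shape}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class _DenseBlock(nn.Module):
    def __init__(self, cfg: BackboneConfig, cin: int, rng, block: str):
        self.convs = []
        self.bns = []
        c = cin
        for _ in range(cfg.layers_per_block):
            self.convs.append(nn.Conv1d(c, cfg.growth_rate, cfg.kernel_size,
                                        rng, block=block))
            self.bns.append(nn.BatchNorm1d(cfg.growth_rate, block=block))
            c += cfg.growth_rate
        self.transition = nn.Conv1d(c, cfg.trunk_channels, 1, rng, block=block)
        self.trans_bn = nn.BatchNorm1d(cfg.trunk_channels, block=block)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        feats = [x]
        for conv, bn in zip(self.convs, self.bns):
            h = nn.concat(feats, axis=1) if len(feats) > 1 else feats[0]
            feats.append(nn.relu(bn(conv(h))))
        return nn.relu(self.trans_bn(self.transition(nn.concat(feats, axis=1))))


class Backbone(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        cin, _ = cfg.input_shape
        self.stem = nn.Conv1d(cin, cfg.trunk_channels, cfg.kernel_size, rng,
                              block="block1")
        self.stem_bn = nn.BatchNorm1d(cfg.trunk_channels, block="block1")
        self.blocks = [
            _DenseBlock(cfg, cfg.trunk_channels, rng, block=f"block{i + 1}")
            for i in range(cfg.n_dense_blocks)
        ]
        self.embed = nn.Linear(cfg.trunk_channels, cfg.embedding_dim, rng,
                               block=f"block{cfg.n_dense_blocks}")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.stem_bn(self.stem(x)))
        for blk in self.blocks:
            h = blk(h)
            if h.shape[2] >= self.cfg.min_pool_length:
                h = nn.avg_pool1d(h, 2)
        return self.embed(nn.global_avg_pool(h))

    def batchnorms(self) -> list[nn.BatchNorm1d]:
        out = [self.stem_bn]
        for blk in self.blocks:
            out.extend(blk.bns)
            out.append(blk.trans_bn)
        return out


class _ProjectionHead(nn.Module):
    """Two-layer ReLU projection head g(.) (SimCLR design)."""

    def __init__(self, din: int, dout: int, rng):
        self.fc1 = nn.Linear(din, din, rng, block="head")
        self.fc2 = nn.Linear(din, dout, rng, block="head")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.relu(self.fc1(x)))


class ModelBundle:
    """Feature extractor plus an optional head and a per-block trainable mask."""

    def __init__(self, backbone: Backbone, head=None, head_kind: str | None = None,
                 seed: int | None = None):
        self.backbone = backbone
        self.head = head
        self.head_kind = head_kind
        self.seed = seed
        self.trainable_mask = [True] * backbone.cfg.n_dense_blocks

    # -- forward -------------------------------------------------------
    def embeddings(self, x: np.ndarray) -> nn.Tensor:
        return self.backbone(nn.Tensor(np.asarray(x, dtype=np.float32),
                                       requires_grad=False))

    def forward(self, x, input_tensor: nn.Tensor | None = None) -> nn.Tensor:
        """Embedding -> head output (logits / projection)."""
        if self.head is None:
            raise RuntimeError("bundle has no head attached")
        inp = input_tensor if input_tensor is not None else nn.Tensor(
            np.asarray(x, dtype=np.float32))
        return self.head(self.backbone(inp))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probability per beat (binary head) or class
        probabilities (k-class head); evaluation mode."""
        self.train(False)
        outs = []
        x = np.asarray(x, dtype=np.float32)
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i : i + batch_size]).data
            if self.head_kind == "binary":
                outs.append(nn.sigmoid(z.reshape(-1)))
            else:
                outs.append(nn.softmax(z))
        return np.concatenate(outs)

    # -- bookkeeping -----------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        params = self.backbone.parameters()
        if self.head is not None:
            params += self.head.parameters()
        return params

    def train(self, mode: bool = True) -> "ModelBundle":
        for bn in self.backbone.batchnorms():
            bn.training = mode
        return self

    def set_trainable_mask(self, mask: list[bool]) -> None:
        cfg = self.backbone.cfg
        if len(mask) != cfg.n_dense_blocks:
            raise ValueError("mask length must equal n_dense_blocks")
        self.trainable_mask = list(mask)
        allowed = {f"block{i + 1}" for i, m in enumerate(mask) if m}
        for p in self.parameters():
            p.requires_grad = p.block == "head" or p.block in allowed

    def trainable_parameters(self) -> list[nn.Parameter]:
        return [p for p in self.parameters() if p.requires_grad]


def build_backbone(config: BackboneConfig, seed: int = 42) -> ModelBundle:
    rng = np.random.default_rng(seed)
    return ModelBundle(Backbone(config, rng), seed=seed)


def attach_head(bundle: ModelBundle, head_kind: str, n_outputs: int = 1,
                seed: int = 0) -> ModelBundle:
    """Attach (or replace) a head: 'binary', 'kclass' or 'projection'."""
    if n_outputs < 1:
        raise ValueError("n_outputs must be >= 1")
    rng = np.random.default_rng(seed)
    din = bundle.backbone.cfg.embedding_dim
    if head_kind == "projection":
        bundle.head = _ProjectionHead(din, n_outputs, rng)
    elif head_kind in ("binary", "kclass"):
        bundle.head = nn.Linear(din, n_outputs, rng, block="head")
    else:
        raise ValueError(f"unknown head kind {head_kind!r}")
    bundle.head_kind = head_kind
    return bundle


def freeze_for_finetune(bundle: ModelBundle,
                        n_trainable_final_blocks: int = 2) -> ModelBundle:
    """Freeze all but the final ``n`` dense blocks (head stays trainable)."""
    n_blocks = bundle.backbone.cfg.n_dense_blocks
    if not 0 <= n_trainable_final_blocks <= n_blocks:
        raise ValueError("n_trainable_final_blocks out of range")
    mask = [i >= n_blocks - n_trainable_final_blocks for i in range(n_blocks)]
    bundle.set_trainable_mask(mask)
    return bundle


def parameter_checksums(bundle: ModelBundle) -> dict[str, float]:
    """Sum of parameter values per freeze group (change detector for tests)."""
    sums: dict[str, float] = {}
    for p in bundle.parameters():
        sums[p.block] = sums.get(p.block, 0.0) + float(np.sum(np.abs(p.data)))
    return sums


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: ModelBundle, path, include_head: bool = False) -> Path:
    """Persist backbone weights (and batch-norm running statistics) plus a
    manifest with the config hash.  The head is excluded by default: after
    pretraining only f(.) transfers."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    params = bundle.backbone.parameters()
    if include_head and bundle.head is not None:
        params += bundle.head.parameters()
    for i, p in enumerate(params):
        arrays[f"p{i:03d}.{p.block}.{p.name}"] = p.data
    for i, bn in enumerate(bundle.backbone.batchnorms()):
        arrays[f"bnstat{i:03d}.mean"] = bn.running_mean
        arrays[f"bnstat{i:03d}.var"] = bn.running_var
    np.savez(path, **arrays)
    manifest = dict(config=asdict(bundle.backbone.cfg),
                    config_hash=bundle.backbone.cfg.hash(),
                    include_head=include_head, head_kind=bundle.head_kind)
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=1))
    return path


def load_checkpoint(path, config: BackboneConfig) -> ModelBundle:
    """Rebuild a head-less bundle from a checkpoint; the stored config hash
    must match ``config``."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    manifest = json.loads(Path(str(path) + ".json").read_text())
    if manifest["config_hash"] != config.hash():
        raise TransferError("checkpoint was produced under a different "
                            "backbone configuration")
    bundle = build_backbone(config, seed=0)
    with np.load(path) as data:
        params = bundle.backbone.parameters()
        keys = sorted(k for k in data.files if k.startswith("p"))[: len(params)]
        for p, k in zip(params, keys):
            p.data = data[k].astype(np.float32).copy()
        for i, bn in enumerate(bundle.backbone.batchnorms()):
            bn.running_mean = data[f"bnstat{i:03d}.mean"].copy()
            bn.running_var = data[f"bnstat{i:03d}.var"].copy()
    return bundle
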