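"""SMOTE oversampling of minority-class beat tensors.

Each synthetic beat is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
x_nn one of the k nearest minority neighbours of x_i (Euclidean distance on
the flattened 12xW vector), i.e. raw-signal interpolation.  Synthetic beats
carry the minority label, a synthetic flag, and are restricted to training
partitions; an automated plausibility gate replaces the paper-style expert
visual review (interpolated Brugada beats must keep their measured J-point
amplitude within the range spanned by their two parents).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .containers import BeatDataset, BeatTensor, BRUGADA_CLASSES
from .preprocess import LeakageError
from .synth import measure_brugada_features


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # target minority:majority ratio
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def smote_oversample(minority_beats: np.ndarray, n_synthetic: int,
                     config: SmoteConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n_synthetic`` interpolated beats.

    Returns (synthetic beats with the input's shape, parent index pairs
    (seed, neighbour)).  Beats may be (N, 12, W) or already flattened (N, D).
    """
    X = np.asarray(minority_beats, dtype=np.float64)
    orig_shape = X.shape[1:]
    flat = X.reshape(len(X), -1)
    if len(flat) <= config.k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={config.k_neighbors} minority samples, "
            f"got {len(flat)}")
    if n_synthetic == 0:
        return (np.empty((0,) + orig_shape), np.empty((0, 2), dtype=np.int64))

    nn_model = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(flat)
    _, nbr = nn_model.kneighbors(flat)
    nbr = nbr[:, 1:]  # drop self

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, len(flat), size=n_synthetic)
    picks = rng.integers(0, config.k_neighbors, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    partners = nbr[seeds, picks]
    synth = flat[seeds] + u[:, None] * (flat[partners] - flat[seeds])
    pairs = np.stack([seeds, partners], axis=1)
    return synth.reshape((n_synthetic,) + orig_shape), pairs


def balance_training_set(train_set: BeatDataset, config: SmoteConfig,
                         partition: str = "train",
                         plausibility_gate: bool = True
                         ) -> tuple[BeatDataset, dict]:
    """Raise the minority (Brugada) beat count to ``target_ratio`` times the
    majority count; majority beats are untouched.

    Returns the augmented training set plus a count report.  Refuses to run
    on anything but a training partition.
    """
    if partition != "train":
        raise LeakageError("SMOTE may only be applied to the training partition")
    y = train_set.binary_targets().astype(bool)
    n_min, n_maj = int(y.sum()), int((~y).sum())
    if n_min == 0 or n_maj == 0:
        raise ValueError("training set must contain both classes")
    if n_min > n_maj:  # 'minority' means the Brugada class here by task design
        raise ValueError("Brugada class is not the minority in this set")

    target = int(round(config.target_ratio * n_maj))
    n_synth = max(0, target - n_min)
    report = dict(minority_before=n_min, majority=n_maj,
                  minority_after=n_min + n_synth, n_synthetic=n_synth,
                  k_neighbors=config.k_neighbors, seed=config.seed)
    if n_synth == 0:
        return train_set, report

    minority = train_set.subset(y)
    if minority.synthetic.any():
        raise LeakageError("minority pool already contains synthetic beats")
    synth, pairs = smote_oversample(minority.beats, n_synth, config)

    if plausibility_gate:
        n_checked = n_failed = 0
        for s, (i, j) in zip(synth, pairs):
            lab = minority.labels[i]
            if lab not in BRUGADA_CLASSES:
                continue
            n_checked += 1
            jp = [measure_brugada_features(
                BeatTensor(v, "x", "x", lab, 0))[0]
                for v in (s, minority.beats[i], minority.beats[j])]
            lo, hi = min(jp[1], jp[2]), max(jp[1], jp[2])
            if not (lo - 1e-9 <= jp[0] <= hi + 1e-9):
                n_failed += 1
        report["plausibility_checked"] = n_checked
        report["plausibility_failed"] = n_failed

    label = minority.labels[pairs[:, 0]]
    aug = BeatDataset(
        synth, label,
        minority.patient_ids[pairs[:, 0]],
        minority.record_ids[pairs[:, 0]],
        np.ones(n_synth, dtype=bool),
    )
    # no-leakage assertion: synthetic provenance stays inside the training set
    if not set(aug.record_ids) <= set(train_set.record_ids):
        raise LeakageError("synthetic beats trace outside the training set")
    return train_set.concat(aug), report
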