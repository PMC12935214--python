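"""Core data containers: ECG records, beat tensors and beat datasets.

Lead order follows the standard 12-lead convention
(I, II, III, aVR, aVL, aVF, V1–V6); signals are in millivolts unless a
record has passed amplitude normalisation, after which units are relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)
LEAD_INDEX: dict[str, int] = {name: i for i, name in enumerate(LEADS)}

CLASSES: tuple[str, ...] = (
    "normal", "rbbb", "brugada_type1", "brugada_type2",
    "early_repol", "anterior_stemi", "hcm_like",
)
#: classes whose records count as positive for the Brugada binary task
BRUGADA_CLASSES: frozenset[str] = frozenset({"brugada_type1", "brugada_type2"})
#: mimic classes used for the false-positive stress test
MIMIC_CLASSES: tuple[str, ...] = ("rbbb", "early_repol", "anterior_stemi", "hcm_like")


@dataclass
class EcgRecord:
    """One patient's continuous 12-lead signal."""

    patient_id: str
    record_id: str
    label: str  # class name or "unlabelled"
    fs_hz: int
    signal: np.ndarray  # (12, T) float, mV
    true_r_peak_samples: np.ndarray | None = None  # generator ground truth

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(LEADS):
            raise ValueError(f"signal must be (12, T), got {self.signal.shape}")
        if self.true_r_peak_samples is not None:
            pk = np.asarray(self.true_r_peak_samples, dtype=np.int64)
            if pk.size and (np.any(np.diff(pk) <= 0) or pk.min() < 0
                            or pk.max() >= self.signal.shape[1]):
                raise ValueError("true_r_peak_samples must be strictly "
                                 "increasing within [0, T)")
            self.true_r_peak_samples = pk

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class BeatTensor:
    """One fixed-length 12-lead beat window centred on an R peak."""

    values: np.ndarray  # (12, W)
    patient_id: str
    record_id: str
    label: str
    r_peak_sample: int  # index of the R peak within the source record

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(LEADS):
            raise ValueError("beat values must be (12, W)")


class BeatDataset:
    """Array-of-struct view over a set of beats, with HDF5 persistence."""

    def __init__(self, beats: np.ndarray, labels: np.ndarray,
                 patient_ids: np.ndarray, record_ids: np.ndarray,
                 synthetic: np.ndarray | None = None):
        self.beats = np.asarray(beats, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=object)
        self.patient_ids = np.asarray(patient_ids, dtype=object)
        self.record_ids = np.asarray(record_ids, dtype=object)
        n = len(self.beats)
        self.synthetic = (np.zeros(n, dtype=bool) if synthetic is None
                          else np.asarray(synthetic, dtype=bool))
        if not (len(self.labels) == len(self.patient_ids)
                == len(self.record_ids) == len(self.synthetic) == n):
            raise ValueError("field lengths disagree")

    def __len__(self) -> int:
        return len(self.beats)

    @classmethod
    def from_beat_tensors(cls, beats: list[BeatTensor]) -> "BeatDataset":
        if not beats:
            raise ValueError("empty beat list")
        return cls(
            np.stack([b.values for b in beats]),
            np.array([b.label for b in beats], dtype=object),
            np.array([b.patient_id for b in beats], dtype=object),
            np.array([b.record_id for b in beats], dtype=object),
        )

    def subset(self, mask: np.ndarray) -> "BeatDataset":
        mask = np.asarray(mask)
        return BeatDataset(self.beats[mask], self.labels[mask],
                           self.patient_ids[mask], self.record_ids[mask],
                           self.synthetic[mask])

    def concat(self, other: "BeatDataset") -> "BeatDataset":
        return BeatDataset(
            np.concatenate([self.beats, other.beats]),
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.patient_ids, other.patient_ids]),
            np.concatenate([self.record_ids, other.record_ids]),
            np.concatenate([self.synthetic, other.synthetic]),
        )

    def binary_targets(self) -> np.ndarray:
        """1 for Brugada-pattern beats, 0 otherwise."""
        return np.array([lbl in BRUGADA_CLASSES for lbl in self.labels],
                        dtype=np.float64)

    # -- persistence ----------------------------------------------------
    def to_hdf5(self, path) -> None:
        str_dt = h5py.string_dtype()
        with h5py.File(path, "w") as f:
            f.create_dataset("beats", data=self.beats)
            f.create_dataset("labels", data=self.labels.astype("O"), dtype=str_dt)
            f.create_dataset("patient_ids", data=self.patient_ids.astype("O"),
                             dtype=str_dt)
            f.create_dataset("record_ids", data=self.record_ids.astype("O"),
                             dtype=str_dt)
            f.create_dataset("synthetic", data=self.synthetic)

    @classmethod
    def from_hdf5(cls, path) -> "BeatDataset":
        with h5py.File(path, "r") as f:
            return cls(
                f["beats"][:],
                np.array([s.decode() for s in f["labels"][:]], dtype=object),
                np.array([s.decode() for s in f["patient_ids"][:]], dtype=object),
                np.array([s.decode() for s in f["record_ids"][:]], dtype=object),
                f["synthetic"][:].astype(bool),
            )
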