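"""ECG preprocessing and patient-level partitioning.

Pipeline order: resample to 100 Hz -> amplitude-normalise -> detect R peaks
-> window one beat per peak (500 ms either side).  Splits and CV folds are
stratified at the patient level so no patient's beats cross partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import LEAD_INDEX, BeatTensor, EcgRecord

TARGET_FS_HZ = 100


class DegenerateSignalError(ValueError):
    pass


class StratificationError(ValueError):
    pass


class LeakageError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Signal-level operations
# ---------------------------------------------------------------------------

def resample_to_target(record: EcgRecord, target_fs_hz: int = TARGET_FS_HZ) -> EcgRecord:
    """Anti-aliased down-sampling to ``target_fs_hz`` (polyphase FIR)."""
    if record.fs_hz < target_fs_hz:
        raise ValueError(
            f"upsampling {record.fs_hz} -> {target_fs_hz} Hz is unsupported")
    if record.fs_hz == target_fs_hz:
        return record
    sig = sps.resample_poly(record.signal, target_fs_hz, record.fs_hz, axis=1)
    peaks = None
    if record.true_r_peak_samples is not None:
        ratio = target_fs_hz / record.fs_hz
        peaks = np.round(record.true_r_peak_samples * ratio).astype(np.int64)
        peaks = np.unique(peaks[(peaks >= 0) & (peaks < sig.shape[1])])
    return EcgRecord(record.patient_id, record.record_id, record.label,
                     target_fs_hz, sig, peaks)


def normalise_amplitude(record: EcgRecord, per_lead: bool = False) -> EcgRecord:
    """Scale so the maximum absolute value is 1.

    Default is one scale per record (inter-lead amplitude ratios, which carry
    diagnostic meaning, are preserved); ``per_lead=True`` normalises each lead
    independently.
    """
    sig = record.signal
    if per_lead:
        denom = np.max(np.abs(sig), axis=1, keepdims=True)
        if np.any(denom == 0):
            raise DegenerateSignalError("flat lead cannot be normalised per lead")
    else:
        denom = np.max(np.abs(sig))
        if denom == 0:
            raise DegenerateSignalError("all-zero record cannot be normalised")
    return EcgRecord(record.patient_id, record.record_id, record.label,
                     record.fs_hz, sig / denom, record.true_r_peak_samples)


def detect_r_peaks(record: EcgRecord, lead: str = "II",
                   refractory_ms: float = 200.0) -> np.ndarray:
    """Pan-Tompkins-style QRS detection on one lead.

    Band-pass (5-15 Hz) -> differentiate -> square -> moving-window integrate
    -> adaptive threshold with a refractory period, then refine each detection
    to the local maximum of the band-passed signal.
    """
    fs = record.fs_hz
    x = record.signal[LEAD_INDEX[lead]]
    if np.ptp(x) < 1e-12:
        return np.array([], dtype=np.int64)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    feat = np.convolve(np.gradient(bp) ** 2, np.ones(int(0.15 * fs)) / (0.15 * fs),
                       mode="same")

    thresh = 0.25 * np.quantile(feat, 0.99)
    refractory = int(refractory_ms / 1000.0 * fs)
    cand, _ = sps.find_peaks(feat, height=thresh, distance=refractory)

    # refine to the R apex: local extremum of |band-passed| signal
    half = int(0.06 * fs)
    peaks = []
    for c in cand:
        a, b = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(a + int(np.argmax(np.abs(bp[a:b]))))
    peaks = np.array(sorted(set(peaks)), dtype=np.int64)
    if peaks.size > 1:  # enforce refractory after refinement
        keep = [0]
        for i in range(1, peaks.size):
            if peaks[i] - peaks[keep[-1]] >= refractory:
                keep.append(i)
        peaks = peaks[keep]
    return peaks


def extract_beats(record: EcgRecord, peaks: np.ndarray,
                  half_window_ms: float = 500.0) -> list[BeatTensor]:
    """Cut one window per peak; peaks too close to an edge are dropped.

    At 100 Hz and the default 500 ms half-window each beat is 100 samples
    (half-open window: samples [peak-50, peak+50))."""
    half = int(round(half_window_ms / 1000.0 * record.fs_hz))
    T = record.n_samples
    beats = []
    for p in np.asarray(peaks, dtype=np.int64):
        if p - half < 0 or p + half > T:
            continue
        beats.append(BeatTensor(values=record.signal[:, p - half : p + half].copy(),
                                patient_id=record.patient_id,
                                record_id=record.record_id,
                                label=record.label, r_peak_sample=int(p)))
    return beats


# ---------------------------------------------------------------------------
# Patient-level partitioning
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train_patients: frozenset[str]
    test_patients: frozenset[str]
    train_fraction: float
    seed: int
    class_counts: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.train_patients & self.test_patients:
            raise LeakageError("train and test patient sets overlap")


def _patient_table(manifest: pd.DataFrame) -> pd.DataFrame:
    tbl = manifest[["patient_id", "label"]].drop_duplicates("patient_id")
    if len(tbl) == 0:
        raise ValueError("empty manifest")
    return tbl


def stratified_patient_split(manifest: pd.DataFrame, train_fraction: float,
                             seed: int = 42) -> DatasetSplit:
    """Patient-level stratified train/test split (class proportions preserved
    within rounding in both partitions)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    tbl = _patient_table(manifest)
    counts = tbl["label"].value_counts()
    if (counts < 2).any():
        raise StratificationError(
            f"classes with <2 patients cannot be stratified: "
            f"{counts[counts < 2].index.tolist()}")
    train_ids, test_ids = train_test_split(
        tbl["patient_id"].to_numpy(), train_size=train_fraction,
        stratify=tbl["label"].to_numpy(), random_state=seed)
    cc = (tbl.assign(part=np.where(tbl["patient_id"].isin(train_ids),
                                   "train", "test"))
             .groupby(["part", "label"]).size().unstack(fill_value=0))
    return DatasetSplit(frozenset(train_ids), frozenset(test_ids),
                        train_fraction, seed, cc)


def make_cv_folds(manifest: pd.DataFrame, k: int, seed: int = 42
                  ) -> list[DatasetSplit]:
    """k patient-disjoint stratified folds; each patient is in exactly one
    validation fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    tbl = _patient_table(manifest)
    counts = tbl["label"].value_counts()
    if (counts < k).any():
        raise StratificationError("every class needs at least k patients")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pids = tbl["patient_id"].to_numpy()
    folds = []
    for tr, va in skf.split(pids, tbl["label"].to_numpy()):
        folds.append(DatasetSplit(frozenset(pids[tr]), frozenset(pids[va]),
                                  1.0 - 1.0 / k, seed))
    return folds


def carve_validation(train_patients: frozenset[str], manifest: pd.DataFrame,
                     val_fraction: float = 0.1, seed: int = 42
                     ) -> tuple[frozenset[str], frozenset[str]]:
    """Patient-level validation carve-out from a training set (early stopping)."""
    tbl = _patient_table(manifest)
    tbl = tbl[tbl["patient_id"].isin(train_patients)]
    counts = tbl["label"].value_counts()
    n_val = max(1, int(round(val_fraction * len(tbl))))
    # stratify only when feasible; tiny carve-outs fall back to random
    strat = (tbl["label"].to_numpy()
             if (counts >= 2).all() and n_val >= len(counts) else None)
    fit_ids, val_ids = train_test_split(
        tbl["patient_id"].to_numpy(), test_size=val_fraction,
        stratify=strat, random_state=seed)
    return frozenset(fit_ids), frozenset(val_ids)


# ---------------------------------------------------------------------------
# End-to-end record -> beats
# ---------------------------------------------------------------------------

def records_to_beats(records: list[EcgRecord], use_true_peaks: bool = False,
                     normalise: bool = True, per_lead: bool = False
                     ) -> list[BeatTensor]:
    """Run the full preprocessing chain over a record collection."""
    beats: list[BeatTensor] = []
    n_dropped = 0
    for rec in records:
        rec = resample_to_target(rec)
        if normalise:
            rec = normalise_amplitude(rec, per_lead=per_lead)
        if use_true_peaks and rec.true_r_peak_samples is not None:
            peaks = rec.true_r_peak_samples
        else:
            peaks = detect_r_peaks(rec)
        got = extract_beats(rec, peaks)
        n_dropped += len(peaks) - len(got)
        beats.extend(got)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} edge peaks during beat extraction",
                      stacklevel=2)
    return beats
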