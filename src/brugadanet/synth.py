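"""Synthetic 12-lead ECG cohort generator.

The generator stands in for hospital ECG databases when benchmarking
training strategies for rare-pattern classification.  Each beat is built
from a three-component cardiac dipole whose P/Q/R/S/T deflections are
sums of Gaussians in time; a fixed 12x3 lead projection turns the dipole
into a coherent 12-lead signal.  Class-discriminative morphology is then
added in lead-voltage space:

* ``rbbb`` — a secondary r' deflection in V1/V2 and a broad terminal S in
  the lateral leads (the classic rsR' mimic of the Brugada pattern);
* ``brugada_type1`` — a coved, downsloping ST-segment elevation with
  T-wave inversion, confined to V1/V2;
* ``brugada_type2`` — a saddleback ST elevation in V1/V2 with a blunter
  r'-ST transition (larger beta angle) and preserved positive T wave;
* ``early_repol`` / ``anterior_stemi`` / ``hcm_like`` — additional
  Brugada-mimic morphologies used only by the stress-test cohort.

The Brugada ST complex is constructed geometrically so that its two
clinical descriptors are recoverable by measurement: the J-point
amplitude (signal above the isoelectric baseline 40 ms after the R peak)
equals ``j_point_amplitude_mV`` by construction, and the beta angle (the
angle between the r' upslope and the ST downslope, measured on standard
ECG paper scaling: 40 ms and 0.1 mV per millimetre) is set by solving
for the downslope that yields ``beta_angle_deg`` against a fixed upslope.

Patient-level latents (heart rate, amplitude scale, morphology jitter)
are drawn once per patient and shared across that patient's records, so
patient-wise leakage in downstream splits is detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import BRUGADA_CLASSES, CLASSES, LEAD_INDEX, LEADS, BeatTensor, EcgRecord


class EmptyCohortError(ValueError):
    pass


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dipole model
# ---------------------------------------------------------------------------

# Lead vectors in a (x: right->left, y: cranial->caudal, z: posterior->anterior)
# frame.  Limb leads live in the frontal (x, y) plane; praecordial leads rotate
# from right-anterior (V1) to left-lateral (V6).
_LEAD_VECTORS = np.array([
    [1.00, 0.00, 0.00],    # I
    [0.50, 0.87, 0.00],    # II
    [-0.50, 0.87, 0.00],   # III
    [-0.75, -0.43, 0.00],  # aVR
    [0.75, -0.43, 0.00],   # aVL
    [0.00, 0.87, 0.00],    # aVF
    [-0.40, 0.05, 0.85],   # V1
    [-0.10, 0.10, 0.95],   # V2
    [0.25, 0.20, 0.85],    # V3
    [0.55, 0.30, 0.60],    # V4
    [0.80, 0.25, 0.30],    # V5
    [0.90, 0.15, 0.05],    # V6
])

# P-QRS-T deflections: (centre ms rel. R, width ms, amplitude mV, direction).
# The mean QRS axis points left-inferior and slightly posterior, which gives
# the usual rS pattern in V1 and qR in V6.
_BASE_WAVES: tuple[tuple[float, float, float, tuple[float, float, float]], ...] = (
    (-170.0, 22.0, 0.12, (0.45, 0.85, -0.10)),   # P
    (-22.0, 6.0, -0.22, (0.60, 0.75, -0.30)),    # Q
    (0.0, 8.0, 1.20, (0.60, 0.75, -0.30)),       # R
    (22.0, 7.0, -0.35, (-0.30, -0.40, 0.86)),    # S (terminal forces, anterior)
    (240.0, 55.0, 0.45, (0.50, 0.70, -0.35)),    # T
)

# ECG paper scaling used for the beta angle: 1 mm = 40 ms = 0.1 mV.
_MM_PER_MV = 10.0
_MS_PER_MM = 40.0
_BETA_UPSLOPE_MM = 2.0  # fixed r' upslope, mm per mm
# r'/ST apex position relative to the R peak; sits past the terminal S wave
# so slope measurements over the flanking 40 ms windows see the tent, not QRS
_RPRIME_PEAK_MS = 80.0
_J_OFFSET_MS = 40.0


def _slope_mm_to_mv_per_ms(s_mm: float) -> float:
    return s_mm / (_MM_PER_MV * _MS_PER_MM)


def beta_angle_from_slopes(s_up_mm: float, s_down_mm: float) -> float:
    """Angle (deg) at the r' apex between the incoming upslope and the
    outgoing ST downslope, both in mm-per-mm paper units; ``s_down_mm > 0``
    denotes a falling segment."""
    v1 = np.array([-1.0, -s_up_mm])
    v2 = np.array([1.0, -s_down_mm])
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def downslope_for_beta(beta_deg: float, s_up_mm: float = _BETA_UPSLOPE_MM) -> float:
    """Solve for the ST downslope (mm/mm, positive = falling) that yields the
    requested beta angle given the fixed r' upslope."""
    lo, hi = 1e-3, 80.0
    blo = beta_angle_from_slopes(s_up_mm, hi)  # steep -> small angle
    bhi = beta_angle_from_slopes(s_up_mm, lo)  # shallow -> large angle
    if not (blo < beta_deg < bhi):
        raise InvalidParameterError(
            f"beta_angle_deg={beta_deg:.1f} outside achievable range "
            f"({blo:.1f}, {bhi:.1f}) for upslope {s_up_mm}")
    return brentq(lambda k: beta_angle_from_slopes(s_up_mm, k) - beta_deg, lo, hi)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    class_label: str
    heart_rate_bpm: float = 70.0
    j_point_amplitude_mV: float = 0.0
    beta_angle_deg: float = 60.0
    rsr_prime_gain: float = 0.0
    drift_amplitude_mV: float = 0.0
    noise_sd_mV: float = 0.0
    amplitude_scale: float = 1.0
    #: per-patient heart-axis rotation (deg about x, y, z) emulating
    #: anatomical orientation variability
    axis_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: per-lead electrode gain factors (12,); None means unit gain
    lead_gain: tuple[float, ...] | None = None
    #: r'/ST apex latency after the R peak (Brugada/RBBB-like classes)
    st_peak_ms: float = 80.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise InvalidParameterError(f"unknown class {self.class_label!r}")
        if self.heart_rate_bpm <= 0:
            raise InvalidParameterError("heart_rate_bpm must be positive")
        if self.drift_amplitude_mV < 0 or self.noise_sd_mV < 0:
            raise InvalidParameterError("nuisance amplitudes must be >= 0")
        if self.rsr_prime_gain < 0:
            raise InvalidParameterError("rsr_prime_gain must be >= 0")
        if self.class_label in BRUGADA_CLASSES and not 0 < self.beta_angle_deg < 180:
            raise InvalidParameterError("beta_angle_deg must lie in (0, 180)")
        if self.class_label == "normal" and self.j_point_amplitude_mV != 0.0:
            raise InvalidParameterError("normal class requires zero J-point amplitude")


#: Class morphology defaults.  The coved (type 1) pattern has a steeper ST
#: downslope (smaller beta) than the saddleback (type 2) pattern.
CLASS_DEFAULTS: dict[str, dict[str, float]] = {
    "normal": dict(),
    "rbbb": dict(rsr_prime_gain=0.55),
    "brugada_type1": dict(j_point_amplitude_mV=0.30, beta_angle_deg=35.0,
                          rsr_prime_gain=0.0),
    "brugada_type2": dict(j_point_amplitude_mV=0.22, beta_angle_deg=80.0,
                          rsr_prime_gain=0.0),
    "early_repol": dict(j_point_amplitude_mV=0.18),
    "anterior_stemi": dict(j_point_amplitude_mV=0.30),
    "hcm_like": dict(rsr_prime_gain=0.0),
}

#: default nuisance variation used by cohort generation: baseline wander and
#: broadband noise at amplitudes typical of resting 12-lead acquisitions
DEFAULT_NUISANCE = dict(drift_amplitude_mV=0.10, noise_sd_mV=0.05)


def default_params(class_label: str, **overrides) -> MorphologyParams:
    kw = dict(CLASS_DEFAULTS[class_label])
    kw.update(overrides)
    return MorphologyParams(class_label=class_label, **kw)


@dataclass(frozen=True)
class CohortSpec:
    class_counts: dict[str, int]
    records_per_patient: int = 1
    #: exact total record count, spread as evenly as possible over patients
    #: (overrides records_per_patient when set)
    records_total: int | None = None
    native_fs_hz: int = 500
    record_duration_s: float = 10.0
    seed: int = 42
    unlabelled: bool = False
    nuisance: dict = field(default_factory=lambda: dict(DEFAULT_NUISANCE))

    def __post_init__(self) -> None:
        if self.records_total is not None and self.records_total < self.total_patients:
            raise InvalidParameterError("records_total smaller than patient count")
        for cls, n in self.class_counts.items():
            if cls not in CLASSES:
                raise InvalidParameterError(f"unknown class {cls!r}")
            if n < 0:
                raise InvalidParameterError("class counts must be >= 0")
        if self.records_per_patient < 1:
            raise InvalidParameterError("records_per_patient must be >= 1")
        if self.native_fs_hz <= 0 or self.record_duration_s <= 0:
            raise InvalidParameterError("sampling rate and duration must be positive")

    @property
    def total_patients(self) -> int:
        return sum(self.class_counts.values())


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def _gauss(t_ms: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - mu) / sigma) ** 2)


def _ramp(t_ms: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    """Linear segment between (t0, v0) and (t1, v1); zero outside [t0, t1]."""
    inside = (t_ms >= t0) & (t_ms < t1)
    out = np.zeros_like(t_ms)
    out[inside] = v0 + (v1 - v0) * (t_ms[inside] - t0) / (t1 - t0)
    return out


def _brugada_st_shape(t_ms: np.ndarray, params: MorphologyParams) -> np.ndarray:
    """r'-ST-T deformation for V1 (per-beat, phase in ms relative to R).

    Piecewise-linear tent whose apex sits at +60 ms: the upslope is fixed at
    2 mm/mm, the downslope solved from ``beta_angle_deg``; the value at
    +40 ms equals ``j_point_amplitude_mV`` exactly.  Type 1 continues into a
    negative T plateau (coved); type 2 settles on a positive saddle.
    """
    apex = params.st_peak_ms
    s_up = _slope_mm_to_mv_per_ms(_BETA_UPSLOPE_MM)
    s_down = _slope_mm_to_mv_per_ms(downslope_for_beta(params.beta_angle_deg))
    peak = params.j_point_amplitude_mV + s_up * (apex - _J_OFFSET_MS)
    t_start = apex - peak / s_up

    if params.class_label == "brugada_type1":
        floor = -0.5 * params.j_point_amplitude_mV  # inverted T plateau
    else:
        floor = 0.35 * params.j_point_amplitude_mV  # saddle level
    t_floor = apex + (peak - floor) / s_down

    shape = _ramp(t_ms, t_start, apex, 0.0, peak)
    shape += _ramp(t_ms, apex, t_floor, peak, floor)
    # plateau after the downslope, released smoothly towards the end of the beat
    t_end = 420.0 if params.class_label == "brugada_type1" else 180.0
    hold = (t_ms >= t_floor) & (t_ms < t_end)
    shape[hold] = floor
    release = t_ms >= t_end
    shape[release] = floor * np.exp(-(t_ms[release] - t_end) / 60.0)
    if params.class_label == "brugada_type2":
        # saddleback: secondary positive hump (the preserved T) after the dip
        shape += 0.8 * params.j_point_amplitude_mV * _gauss(t_ms, 260.0, 50.0)
    return shape


def _class_deformation(t_ms: np.ndarray, params: MorphologyParams) -> np.ndarray:
    """Lead-space (12, len(t)) additive deformation for one beat."""
    d = np.zeros((len(LEADS), len(t_ms)))
    cls = params.class_label
    if cls == "rbbb":
        centre = params.st_peak_ms - 32.0
        rprime = params.rsr_prime_gain * _gauss(t_ms, centre, 11.0)
        d[LEAD_INDEX["V1"]] += rprime
        d[LEAD_INDEX["V2"]] += 0.6 * rprime
        slur = -0.45 * params.rsr_prime_gain * _gauss(t_ms, centre + 7.0, 16.0)
        for lead in ("I", "V5", "V6"):
            d[LEAD_INDEX[lead]] += slur
        # mild secondary repolarisation ST shift in V1/V2 (overlaps with
        # near-threshold Brugada cases, the clinically confusable zone)
        if params.j_point_amplitude_mV:
            st = params.j_point_amplitude_mV * _gauss(t_ms, 80.0, 45.0)
            d[LEAD_INDEX["V1"]] += st
            d[LEAD_INDEX["V2"]] += 0.6 * st
    elif cls in BRUGADA_CLASSES:
        st = _brugada_st_shape(t_ms, params)
        d[LEAD_INDEX["V1"]] += st
        d[LEAD_INDEX["V2"]] += 0.7 * st
        if params.rsr_prime_gain:
            # many Brugada patients carry an RBBB-like r' as well
            rprime = params.rsr_prime_gain * _gauss(t_ms, 45.0, 11.0)
            d[LEAD_INDEX["V1"]] += rprime
            d[LEAD_INDEX["V2"]] += 0.6 * rprime
    elif cls == "normal" and params.rsr_prime_gain:
        # rSr' normal variant (incomplete-RBBB-like appearance in V1)
        rprime = params.rsr_prime_gain * _gauss(t_ms, 45.0, 10.0)
        d[LEAD_INDEX["V1"]] += rprime
        d[LEAD_INDEX["V2"]] += 0.6 * rprime
    elif cls == "early_repol":
        j = params.j_point_amplitude_mV
        notch = j * _gauss(t_ms, 45.0, 9.0)
        st = 0.7 * j * _gauss(t_ms, 110.0, 55.0)
        for lead in ("II", "V4", "V5", "V6"):
            d[LEAD_INDEX[lead]] += notch + st
    elif cls == "anterior_stemi":
        j = params.j_point_amplitude_mV
        st = j * _gauss(t_ms, 110.0, 75.0)
        for lead in ("V1", "V2", "V3", "V4"):
            d[LEAD_INDEX[lead]] += st
        for lead in ("II", "III", "aVF"):
            d[LEAD_INDEX[lead]] -= 0.35 * st
    elif cls == "hcm_like":
        tinv = -0.35 * _gauss(t_ms, 240.0, 55.0)
        for lead in ("I", "V4", "V5", "V6"):
            d[LEAD_INDEX[lead]] += tinv
    return d


def _qrs_scale(params: MorphologyParams) -> float:
    # hcm_like carries high QRS voltage
    return 1.6 if params.class_label == "hcm_like" else 1.0


def _rotation_matrix(deg: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = np.radians(deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def generate_record(params: MorphologyParams, fs_hz: int = 500,
                    duration_s: float = 10.0, rng_seed: int = 0,
                    patient_id: str = "P0", record_id: str = "R0",
                    label: str | None = None) -> EcgRecord:
    """Simulate one continuous 12-lead record; identical arguments produce a
    bit-identical record."""
    if fs_hz < 100:
        raise InvalidParameterError("fs_hz must be >= 100")
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    if duration_s < 2.0 / (params.heart_rate_bpm / 60.0):
        raise InvalidParameterError("duration too short to contain one full beat")

    rng = np.random.default_rng(rng_seed)
    T = int(round(fs_hz * duration_s))
    t_s = np.arange(T) / fs_hz

    # R-peak train with mild RR jitter
    rr_mean = 60.0 / params.heart_rate_bpm
    r_times = [0.45 * rr_mean + 0.25]
    while True:
        nxt = r_times[-1] + rr_mean * (1.0 + 0.03 * rng.standard_normal())
        if nxt >= duration_s - 0.05:
            break
        r_times.append(nxt)
    r_times = np.array(r_times)

    signal = np.zeros((len(LEADS), T))
    qrs_gain = _qrs_scale(params)
    lead_vectors = _LEAD_VECTORS @ _rotation_matrix(params.axis_rotation_deg).T
    for r_t in r_times:
        t_ms = (t_s - r_t) * 1000.0
        active = (t_ms > -450.0) & (t_ms < 520.0)
        tm = t_ms[active]
        beat = np.zeros((len(LEADS), tm.size))
        for mu, sigma, amp, direction in _BASE_WAVES:
            a = amp * (qrs_gain if abs(mu) < 60.0 else 1.0)
            lead_amp = lead_vectors @ (a * np.asarray(direction))
            beat += lead_amp[:, None] * _gauss(tm, mu, sigma)[None, :]
        beat += _class_deformation(tm, params)
        signal[:, active] += params.amplitude_scale * beat
    if params.lead_gain is not None:
        signal *= np.asarray(params.lead_gain)[:, None]

    if params.drift_amplitude_mV > 0:
        f = rng.uniform(0.1, 0.35)
        phase = rng.uniform(0, 2 * np.pi)
        signal += params.drift_amplitude_mV * np.sin(2 * np.pi * f * t_s + phase)[None, :]
    if params.noise_sd_mV > 0:
        # per-lead noise heterogeneity (electrode contact quality varies)
        sd = params.noise_sd_mV * rng.uniform(0.5, 2.0, size=len(LEADS))
        signal += rng.normal(0.0, 1.0, size=signal.shape) * sd[:, None]

    peaks = np.round(r_times * fs_hz).astype(np.int64)
    peaks = peaks[(peaks >= 0) & (peaks < T)]
    return EcgRecord(patient_id=patient_id, record_id=record_id,
                     label=label if label is not None else params.class_label,
                     fs_hz=fs_hz, signal=signal, true_r_peak_samples=peaks)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _patient_params(class_label: str, rng: np.random.Generator,
                    nuisance: dict) -> MorphologyParams:
    """Draw one patient's latent morphology around the class defaults."""
    base = dict(CLASS_DEFAULTS[class_label])
    hr = float(np.clip(rng.normal(70.0, 8.0), 48.0, 110.0))
    kw: dict = dict(
        heart_rate_bpm=hr,
        amplitude_scale=float(np.clip(rng.normal(1.0, 0.10), 0.6, 1.4)),
        axis_rotation_deg=tuple(rng.normal(0.0, 8.0, size=3)),
        lead_gain=tuple(np.clip(rng.normal(1.0, 0.10, size=12), 0.7, 1.3)),
        **nuisance)
    if class_label in BRUGADA_CLASSES:
        # broad amplitude heterogeneity: some patients sit near the
        # diagnostic threshold, as in real Brugada populations
        kw["j_point_amplitude_mV"] = base["j_point_amplitude_mV"] * float(
            np.clip(rng.lognormal(0.0, 0.45), 0.3, 1.8))
        kw["beta_angle_deg"] = float(np.clip(
            base["beta_angle_deg"] + rng.normal(0.0, 5.0), 30.0, 110.0))
        kw["st_peak_ms"] = float(rng.uniform(65.0, 95.0))
        kw["rsr_prime_gain"] = float(rng.uniform(0.0, 0.5))
    elif class_label == "rbbb":
        # right-skewed secondary ST shift: most RBBB near zero, a tail
        # reaching the near-threshold Brugada range
        kw["j_point_amplitude_mV"] = 0.18 * float(rng.uniform(0.0, 1.0)) ** 2
        kw["st_peak_ms"] = float(rng.uniform(68.0, 95.0))
    elif base.get("j_point_amplitude_mV"):
        kw["j_point_amplitude_mV"] = base["j_point_amplitude_mV"] * float(
            np.clip(rng.normal(1.0, 0.12), 0.6, 1.4))
    if class_label == "normal" and rng.uniform() < 0.3:
        # rSr' normal variant subpopulation
        kw["rsr_prime_gain"] = float(rng.uniform(0.05, 0.30))
    if base.get("rsr_prime_gain"):
        kw["rsr_prime_gain"] = base["rsr_prime_gain"] * float(
            np.clip(rng.lognormal(0.0, 0.40), 0.35, 2.0))
    return MorphologyParams(class_label=class_label, **kw)


def _records_per_patient(spec: CohortSpec) -> list[int]:
    n_pat = spec.total_patients
    if spec.records_total is None:
        return [spec.records_per_patient] * n_pat
    base, extra = divmod(spec.records_total, n_pat)
    return [base + (1 if i < extra else 0) for i in range(n_pat)]


def generate_cohort(spec: CohortSpec, out_dir=None, materialise: bool = True
                    ) -> tuple[pd.DataFrame, list[EcgRecord]]:
    """Generate a patient cohort; returns (manifest, records).

    The manifest has one row per record (patient_id, record_id, label, path).
    When ``out_dir`` is given every record is persisted in WFDB format and
    ``path`` points at its header file; otherwise ``path`` is empty.  With
    ``materialise=False`` only the manifest is built (identical ids/labels,
    no signal synthesis) — useful for cohort-arithmetic checks at full study
    scale.
    """
    if spec.total_patients == 0:
        raise EmptyCohortError("cohort spec contains zero patients")

    ss = np.random.SeedSequence(spec.seed)
    per_patient = _records_per_patient(spec)
    rows = []
    records: list[EcgRecord] = []
    pidx = 0
    for cls in CLASSES:
        n = spec.class_counts.get(cls, 0)
        for _ in range(n):
            child = ss.spawn(1)[0]
            prng = np.random.default_rng(child)
            params = _patient_params(cls, prng, spec.nuisance)
            patient_id = f"pt{pidx:05d}"
            label = "unlabelled" if spec.unlabelled else cls
            for k in range(per_patient[pidx]):
                record_id = f"{patient_id}r{k:02d}"
                rec_seed = int(prng.integers(0, 2**31 - 1))
                # per-record heart-rate wobble around the patient latent
                updates = dict(heart_rate_bpm=float(np.clip(
                    params.heart_rate_bpm + prng.normal(0.0, 2.0), 45.0, 115.0)))
                if cls in BRUGADA_CLASSES:
                    # the Brugada pattern waxes and wanes between recordings,
                    # down to near-concealed expression
                    updates["j_point_amplitude_mV"] = (
                        params.j_point_amplitude_mV * float(prng.uniform(0.15, 1.0)))
                rec_params = replace(params, **updates)
                path = ""
                if materialise:
                    rec = generate_record(
                        rec_params, fs_hz=spec.native_fs_hz,
                        duration_s=spec.record_duration_s, rng_seed=rec_seed,
                        patient_id=patient_id, record_id=record_id, label=label)
                    if out_dir is not None:
                        from .io_wfdb import write_record
                        path = str(write_record(rec, out_dir))
                    records.append(rec)
                rows.append(dict(patient_id=patient_id, record_id=record_id,
                                 label=label, path=path))
            pidx += 1
    manifest = pd.DataFrame(rows, columns=["patient_id", "record_id", "label", "path"])
    return manifest, records


# ---------------------------------------------------------------------------
# Feature measurement (round-trip oracle for the generator)
# ---------------------------------------------------------------------------

def measure_brugada_features(beat: BeatTensor, lead: str = "V1",
                             fs_hz: int = 100) -> tuple[float, float]:
    """Measure (J-point amplitude mV, beta angle deg) on a beat window.

    The beat must be R-centred.  Baseline is the mean of the PR segment
    (-130..-80 ms); the J point is read 40 ms after the R peak; the beta
    angle is formed by two-point slopes over the 40 ms segments either side
    of the r'/ST apex (searched in +20..+90 ms), on standard paper scaling.
    A flat lead returns (0.0, nan).
    """
    v = beat.values[LEAD_INDEX[lead]]
    c = beat.values.shape[1] // 2
    ms = 1000.0 / fs_hz  # ms per sample
    seg = lambda a, b: slice(c + int(round(a / ms)), c + int(round(b / ms)) + 1)

    if np.ptp(v) < 1e-9:
        return 0.0, float("nan")

    baseline = float(np.mean(v[seg(-130, -80)]))
    j_amp = float(v[c + int(round(_J_OFFSET_MS / ms))] - baseline)

    lo, hi = c + int(round(20 / ms)), c + int(round(110 / ms))
    p = lo + int(np.argmax(v[lo:hi + 1]))
    w = int(round(40.0 / ms))
    if p - w < 0 or p + w >= v.size:
        return j_amp, float("nan")
    rise_mm = (v[p] - v[p - w]) * _MM_PER_MV
    fall_mm = (v[p] - v[p + w]) * _MM_PER_MV
    # 40 ms = 1 mm horizontally
    beta = beta_angle_from_slopes(rise_mm, fall_mm)
    return j_amp, float(beta)
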