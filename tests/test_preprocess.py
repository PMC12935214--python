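"""Resampling, normalisation, R-peak detection, beat windowing and
patient-level partitioning."""

import numpy as np
import pandas as pd
import pytest

from brugadanet.containers import EcgRecord, LEADS
from brugadanet.preprocess import (DegenerateSignalError, StratificationError,
                                   detect_r_peaks, extract_beats,
                                   make_cv_folds, normalise_amplitude,
                                   resample_to_target,
                                   stratified_patient_split)
from brugadanet.synth import CohortSpec, default_params, generate_cohort, generate_record


def _sine_record(freq_hz=5.0, fs=500, duration=10.0):
    t = np.arange(int(fs * duration)) / fs
    sig = np.tile(np.sin(2 * np.pi * freq_hz * t), (12, 1))
    return EcgRecord("p", "r", "normal", fs, sig)


class TestResample:
    def test_length_scales_with_rate_ratio(self):
        rec = resample_to_target(_sine_record())
        assert rec.fs_hz == 100
        assert rec.signal.shape == (12, 1000)

    def test_identity_at_target_rate(self):
        rec = _sine_record(fs=100, duration=5.0)
        assert resample_to_target(rec) is rec

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to_target(_sine_record(fs=80, duration=5.0))

    def test_spectral_peak_preserved(self):
        rec = resample_to_target(_sine_record(freq_hz=5.0))
        spec = np.abs(np.fft.rfft(rec.signal[0]))
        freqs = np.fft.rfftfreq(rec.n_samples, d=1 / 100)
        assert freqs[int(np.argmax(spec))] == pytest.approx(5.0, abs=0.1)

    def test_true_peaks_rescaled(self):
        rec = generate_record(default_params("normal", heart_rate_bpm=60.0),
                              500, 10.0, rng_seed=0)
        out = resample_to_target(rec)
        assert np.array_equal(out.true_r_peak_samples,
                              np.round(rec.true_r_peak_samples / 5).astype(int))


class TestNormalise:
    def test_max_abs_is_one_and_ratios_preserved(self):
        rec = _sine_record()
        rec.signal *= np.linspace(0.5, 2.0, 12)[:, None]
        out = normalise_amplitude(rec)
        assert np.max(np.abs(out.signal)) == pytest.approx(1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_in = rec.signal[3] / rec.signal[7]
            r_out = out.signal[3] / out.signal[7]
        assert np.nanmax(np.abs(r_in - r_out)) < 1e-9

    def test_scale_invariance(self):
        rec = _sine_record()
        scaled = EcgRecord("p", "r", "normal", rec.fs_hz, rec.signal * 3.0)
        a = normalise_amplitude(rec).signal
        b = normalise_amplitude(scaled).signal
        assert np.allclose(a, b)

    def test_all_zero_rejected(self):
        rec = EcgRecord("p", "r", "normal", 100, np.zeros((12, 100)))
        with pytest.raises(DegenerateSignalError):
            normalise_amplitude(rec)


class TestRPeakDetection:
    def _prepared(self, cls="normal", seed=0, hr=60.0):
        p = default_params(cls, heart_rate_bpm=hr, drift_amplitude_mV=0.1,
                           noise_sd_mV=0.05)
        rec = generate_record(p, 500, 10.0, rng_seed=seed)
        return normalise_amplitude(resample_to_target(rec))

    @pytest.mark.parametrize("cls", ["normal", "rbbb", "brugada_type1"])
    def test_detections_match_ground_truth_within_50ms(self, cls):
        rec = self._prepared(cls)
        det = detect_r_peaks(rec)
        truth = rec.true_r_peak_samples
        assert abs(len(det) - len(truth)) <= 1
        for d in det:
            assert min(abs(int(d) - truth)) <= 5  # 50 ms at 100 Hz

    def test_flat_signal_yields_no_detections(self):
        rec = EcgRecord("p", "r", "normal", 100, np.zeros((12, 500)))
        assert len(detect_r_peaks(rec)) == 0

    def test_refractory_spacing(self):
        rec = self._prepared(seed=3, hr=90.0)
        det = detect_r_peaks(rec)
        assert np.all(np.diff(det) >= 20)


class TestExtractBeats:
    def test_window_length_100_at_100hz(self):
        rec = self._record()
        beats = extract_beats(rec, rec.true_r_peak_samples)
        assert all(b.values.shape == (12, 100) for b in beats)
        assert all(b.label == rec.label for b in beats)

    def test_edge_peaks_dropped(self):
        rec = self._record()
        n_interior = len(extract_beats(rec, rec.true_r_peak_samples))
        with_edge = np.concatenate([[10], rec.true_r_peak_samples])
        assert len(extract_beats(rec, with_edge)) == n_interior

    @staticmethod
    def _record():
        rec = generate_record(default_params("normal", heart_rate_bpm=60.0),
                              500, 10.0, rng_seed=1)
        return resample_to_target(rec)


@pytest.fixture(scope="module")
def study_manifest():
    spec = CohortSpec(class_counts={"normal": 352, "rbbb": 176,
                                    "brugada_type1": 88, "brugada_type2": 88},
                      seed=42)
    manifest, _ = generate_cohort(spec, materialise=False)
    return manifest


class TestSplits:
    def test_scarce_split_yields_44_brugada_training_patients(self, study_manifest):
        split = stratified_patient_split(study_manifest, 0.25, seed=42)
        labels = study_manifest.set_index("patient_id")["label"]
        train_labels = labels.loc[sorted(split.train_patients)]
        n_brugada = train_labels.isin(["brugada_type1", "brugada_type2"]).sum()
        assert n_brugada == 44

    def test_three_to_one_class_ratio_in_both_partitions(self, study_manifest):
        split = stratified_patient_split(study_manifest, 0.25, seed=42)
        labels = study_manifest.set_index("patient_id")["label"]
        for part in (split.train_patients, split.test_patients):
            sub = labels.loc[sorted(part)]
            brugada = sub.isin(["brugada_type1", "brugada_type2"]).sum()
            assert (len(sub) - brugada) / brugada == pytest.approx(3.0)

    def test_split_deterministic(self, study_manifest):
        a = stratified_patient_split(study_manifest, 0.25, seed=42)
        b = stratified_patient_split(study_manifest, 0.25, seed=42)
        assert a.train_patients == b.train_patients

    def test_no_patient_leakage_over_100_seeds(self, study_manifest):
        all_patients = set(study_manifest["patient_id"])
        for seed in range(100):
            s = stratified_patient_split(study_manifest, 0.25, seed=seed)
            assert not (s.train_patients & s.test_patients)
            assert s.train_patients | s.test_patients == all_patients

    def test_tiny_class_rejected(self):
        manifest = pd.DataFrame(dict(patient_id=["a", "b", "c"],
                                     record_id=["a0", "b0", "c0"],
                                     label=["normal", "normal", "rbbb"]))
        with pytest.raises(StratificationError):
            stratified_patient_split(manifest, 0.5, seed=0)

    def test_invalid_fraction_rejected(self, study_manifest):
        with pytest.raises(ValueError):
            stratified_patient_split(study_manifest, 1.5, seed=0)


class TestCvFolds:
    def test_folds_partition_patients(self, study_manifest):
        folds = make_cv_folds(study_manifest, 5, seed=42)
        val_sets = [f.test_patients for f in folds]
        union = set().union(*val_sets)
        assert union == set(study_manifest["patient_id"])
        assert sum(len(v) for v in val_sets) == len(union)  # disjoint

    def test_fold_stratification_within_one_patient(self, study_manifest):
        folds = make_cv_folds(study_manifest, 4, seed=0)
        labels = study_manifest.set_index("patient_id")["label"]
        for f in folds:
            sub = labels.loc[sorted(f.test_patients)]
            counts = sub.value_counts()
            assert abs(counts.get("brugada_type1", 0) - 88 / 4) <= 1

    def test_k_exceeding_class_size_rejected(self):
        manifest = pd.DataFrame(dict(
            patient_id=[f"p{i}" for i in range(6)],
            record_id=[f"p{i}r" for i in range(6)],
            label=["normal"] * 4 + ["rbbb"] * 2))
        with pytest.raises(StratificationError):
            make_cv_folds(manifest, 3, seed=0)
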