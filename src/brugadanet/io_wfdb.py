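"""Minimal WFDB record IO (format 16, one interleaved .dat per record).

Covers the subset of the WFDB specification this pipeline needs: a header
(.hea) with a record line and one signal line per lead, and a little-endian
16-bit sample-interleaved .dat file.  Metadata that WFDB has no field for
(patient id, class label, ground-truth R peaks) is carried in ``#`` comment
lines, which WFDB-compliant readers ignore.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import LEADS, EcgRecord

_GAIN = 1000.0  # ADC units per mV; int16 range then spans +/-32.7 mV
_FMT = 16


def write_record(record: EcgRecord, out_dir) -> Path:
    """Write ``record`` as <record_id>.hea/.dat under ``out_dir``; returns the
    header path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    n_sig, n_samp = record.signal.shape

    adc = np.round(record.signal * _GAIN)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds int16 range at gain 1000 adu/mV")
    adc = adc.astype("<i2")

    lines = [f"{name} {n_sig} {record.fs_hz} {n_samp}"]
    for lead in LEADS:
        lines.append(f"{name}.dat {_FMT} {_GAIN:g}(0)/mV 16 0 0 0 0 {lead}")
    lines.append(f"# patient_id: {record.patient_id}")
    lines.append(f"# label: {record.label}")
    if record.true_r_peak_samples is not None:
        peaks = " ".join(str(int(p)) for p in record.true_r_peak_samples)
        lines.append(f"# true_r_peaks: {peaks}")

    hea = out_dir / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    # sample-major interleaving: frame i holds one sample from each signal
    adc.T.tofile(out_dir / f"{name}.dat")
    return hea


def read_record(hea_path) -> EcgRecord:
    """Read a record written by :func:`write_record` (or any single-.dat,
    format-16, constant-gain WFDB record)."""
    hea_path = Path(hea_path)
    lines = hea_path.read_text().splitlines()
    head = lines[0].split()
    name, n_sig, fs, n_samp = head[0], int(head[1]), int(float(head[2])), int(head[3])

    gains = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if int(parts[1]) != _FMT:
            raise ValueError(f"unsupported WFDB format {parts[1]}")
        gain_field = parts[2].split("/")[0]
        gains.append(float(gain_field.split("(")[0]))

    patient_id, label, peaks = name, "unlabelled", None
    for ln in lines[1 + n_sig:]:
        if ln.startswith("# patient_id:"):
            patient_id = ln.split(":", 1)[1].strip()
        elif ln.startswith("# label:"):
            label = ln.split(":", 1)[1].strip()
        elif ln.startswith("# true_r_peaks:"):
            vals = ln.split(":", 1)[1].split()
            peaks = np.array([int(v) for v in vals], dtype=np.int64)

    raw = np.fromfile(hea_path.with_suffix(".dat"), dtype="<i2")
    sig = raw.reshape(n_samp, n_sig).T.astype(np.float64)
    sig /= np.asarray(gains)[:, None]
    return EcgRecord(patient_id=patient_id, record_id=name, label=label,
                     fs_hz=fs, signal=sig, true_r_peak_samples=peaks)
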