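#!/usr/bin/env python
"""Preprocess the generated cohorts into beat datasets.

Reads the WFDB records written by 01_generate_cohorts.py, resamples to
100 Hz, normalises amplitude, detects R peaks (Pan-Tompkins style) and cuts
1 s beat windows; each cohort becomes one HDF5 beat container with a JSON
provenance sidecar under results/beats/.
"""

import json
from pathlib import Path

import pandas as pd

from brugadanet.containers import BeatDataset
from brugadanet.io_wfdb import read_record
from brugadanet.preprocess import records_to_beats

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out_dir = ROOT / "beats"
    out_dir.mkdir(parents=True, exist_ok=True)
    for manifest_path in sorted((ROOT / "cohorts").glob("*_manifest.csv")):
        name = manifest_path.stem.replace("_manifest", "")
        manifest = pd.read_csv(manifest_path)
        records = [read_record(p) for p in manifest["path"]]
        beats = BeatDataset.from_beat_tensors(records_to_beats(records))
        h5 = out_dir / f"{name}_beats.h5"
        beats.to_hdf5(h5)
        sidecar = dict(cohort=name, n_records=len(records),
                       n_beats=len(beats), fs_hz=100, window_samples=100,
                       normalisation="per-record max-abs",
                       source_manifest=str(manifest_path))
        (out_dir / f"{name}_beats.json").write_text(json.dumps(sidecar,
                                                               indent=1))
        print(f"{name:>10}: {len(records):4d} records -> {len(beats):5d} "
              f"beats -> {h5}")


if __name__ == "__main__":
    main()
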