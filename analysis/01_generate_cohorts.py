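#!/usr/bin/env python
"""Generate the four synthetic study cohorts at desk scale.

Emulates the study layout — a labelled baseline cohort (normal / RBBB /
Brugada), a large normal-vs-RBBB pretraining cohort, an unlabelled
Brugada-patient cohort and a Brugada-mimic stress-test cohort — and writes
each record in WFDB format plus one manifest CSV per cohort under
results/cohorts/.
"""

from pathlib import Path

from brugadanet.pipeline import make_fixtures

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"


def main() -> None:
    cohorts = make_fixtures("tiny", seed=42, out_dir=OUT)
    for name, (manifest, records) in cohorts.items():
        manifest.to_csv(OUT / f"{name}_manifest.csv", index=False)
        n_pat = manifest["patient_id"].nunique()
        print(f"{name:>10}: {len(manifest):4d} records from {n_pat:4d} "
              f"patients -> {OUT / name}")
    print("\nStudy-shaped cohort sizes (manifests only):")
    for name, (manifest, _) in make_fixtures("paper_shape", seed=42).items():
        print(f"{name:>10}: {len(manifest):6d} records / "
              f"{manifest['patient_id'].nunique():6d} patients")


if __name__ == "__main__":
    main()
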