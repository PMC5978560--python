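#!/usr/bin/env python
"""Reconstruct the delivered dose for a synthetic cohort.

Runs the full per-patient flow (rigid + deformable registration, mCBCT,
contour propagation, surrogate dose with frozen normalisation, inverse-field
warping, accumulation) for every patient and writes one row per gland per
dose type to ``results/cohort_metrics.csv``.  The default full 7-week
70 Gy course takes a couple of minutes per patient at the compact grid.  Patients in the 'xerostomia'
arm are simulated with a larger medial gland drift, so their delivered dose
rises more.
"""

import argparse
import dataclasses
from pathlib import Path

from doseaccum.benchmarks import e2e_config, patient_seed
from doseaccum.pipeline import records_to_csv, run_patient


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-patients", type=int, default=6)
    ap.add_argument("--n-weeks", type=int, default=7)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort_metrics.csv"))
    args = ap.parse_args()

    records = []
    for i in range(1, args.n_patients + 1):
        xero = i <= args.n_patients // 2
        cfg = e2e_config(patient_seed(args.seed, 200 + i), n_weeks=args.n_weeks)
        cfg = dataclasses.replace(
            cfg,
            patient_id=f"P{i:02d}",
            xerostomia=xero,
            course=dataclasses.replace(
                cfg.course, medial_drift_mm=6.0 if xero else 3.0
            ),
        )
        print(f"reconstructing {cfg.patient_id} (xerostomia={xero}) ...")
        result = run_patient(cfg)
        records.extend(result.records)
        for r in result.records:
            print(
                f"  {r.side}: planned Dmean {r.planned.dmean_gy:5.2f} Gy -> "
                f"delivered {r.delivered.dmean_gy:5.2f} Gy"
            )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    records_to_csv(records, args.out)
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
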