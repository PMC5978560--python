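#!/usr/bin/env python
"""Simulate a synthetic head-and-neck cohort and summarise its properties.

Builds one phantom per patient, simulates the weekly CBCT course with known
ground-truth deformations, and records gland volumes, realized parotid
shrinkage and deformation-field health (minimum Jacobian determinant) in
``results/cohort_simulation.csv``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from doseaccum.benchmarks import e2e_config, patient_seed
from doseaccum.synthetic import build_phantom, simulate_course


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-patients", type=int, default=6)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort_simulation.csv"))
    args = ap.parse_args()

    rows = []
    for i in range(1, args.n_patients + 1):
        seed = patient_seed(args.seed, i)
        cfg = e2e_config(seed)
        ct, masks = build_phantom(cfg.phantom, seed=seed)
        studies = simulate_course(ct, masks, cfg.course, cfg.degrade)
        final = studies[-1]
        for g in ("PG_L", "PG_R"):
            pre = masks[g].volume_cc
            post = final.gt_masks[g].volume_cc
            rows.append(
                {
                    "patient": f"P{i:02d}",
                    "gland": g,
                    "pre_volume_cc": pre,
                    "post_volume_cc": post,
                    "realized_reduction_pct": 100.0 * (pre - post) / pre,
                    "min_jacobian_det": float(
                        final.gt_field.jacobian_determinant().min()
                    ),
                    "max_displacement_mm": float(final.gt_field.magnitude().max()),
                }
            )
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.4g")
    print(df.to_string(index=False))
    print(
        f"\nMean realized parotid volume reduction: "
        f"{df['realized_reduction_pct'].mean():.1f}% "
        f"(requested {100 * 0.135:.1f}%); all fields invertible: "
        f"{bool((df['min_jacobian_det'] > 0).all())}"
    )


if __name__ == "__main__":
    main()
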