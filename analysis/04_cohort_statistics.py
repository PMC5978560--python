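#!/usr/bin/env python
"""Cohort statistics over the reconstructed metrics.

Reads ``results/cohort_metrics.csv`` (written by 03_reconstruct_delivered_dose.py),
rebuilds the gland records and emits the paired planning-vs-delivered table,
the per-group planning/delivered tables with tolerance references, the
volume-change table and both relative-change summaries, as CSVs plus a
markdown report under ``results/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from doseaccum.metrics import DoseMetrics
from doseaccum.stats import CohortRecord, report_markdown, summarize_cohort


def records_from_csv(path: Path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    records = []
    for (pid, side), sub in df.groupby(["patient_id", "side"]):
        by_type = {row["dose_type"]: row for _, row in sub.iterrows()}

        def metrics(row) -> DoseMetrics:
            return DoseMetrics(
                row["V20"], row["V30"], row["V40"], row["D50"], row["Dmean"],
                row["volume_cc"],
            )

        planned = by_type["planned"]
        records.append(
            CohortRecord(
                patient_id=pid,
                side=side,
                xerostomia=bool(planned["xerostomia"]),
                planned=metrics(planned),
                delivered=metrics(by_type["delivered"]),
                pre_volume_cc=planned["pre_volume_cc"],
                post_volume_cc=planned["post_volume_cc"],
            )
        )
    return records


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--metrics", type=Path, default=Path("results/cohort_metrics.csv")
    )
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = records_from_csv(args.metrics)
    tables = summarize_cohort(records)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(args.out_dir / f"table_{name}.csv", index=False)
    report = report_markdown(tables)
    (args.out_dir / "report.md").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
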