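"""Cohort statistics: planning-vs-delivered and xerostomia-group comparisons.

Paired t-tests (with Pearson correlation) relate each gland's planned and
delivered endpoint; independent two-sample t-tests (classical pooled
primary, Welch alongside) compare patients who developed xerostomia with
those who did not.  Two-sided p-values, alpha = 0.05, no multiple-testing
correction in the primary columns — a Holm-adjusted column is emitted as a
clearly-marked extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import DoseMetrics

ENDPOINTS = ("V20", "V30", "V40", "D50", "Dmean")
#: parotid radiation tolerance references (Gy); NA for the Vx endpoints
TOLERANCE_REF = {"D50": 30.0, "Dmean": 26.0}


class DegenerateDataError(ValueError):
    """Zero variance where the test statistic needs spread."""


class SampleSizeError(ValueError):
    """Too few observations for the requested test."""


class GroupingError(ValueError):
    """A comparison group is empty."""


@dataclass
class CohortRecord:
    """One parotid gland of one synthetic patient."""

    patient_id: str
    side: str                       # "L" or "R"
    xerostomia: bool
    planned: DoseMetrics
    delivered: DoseMetrics
    pre_volume_cc: float
    post_volume_cc: float

    def __post_init__(self) -> None:
        if self.pre_volume_cc <= 0 or self.post_volume_cc <= 0:
            raise ValueError("gland volumes must be positive")


@dataclass
class ComparisonResult:
    label: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: float
    p: float
    kind: str                        # paired | independent-pooled | independent-welch
    correlation: float | None = None # paired mode only


def paired_compare(a, b, label: str = "") -> ComparisonResult:
    """Paired t-test of ``a`` vs ``b`` with the Pearson correlation alongside.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and ``df = n-1``;
    sample SDs use the n-1 denominator throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 3:
        raise SampleSizeError(f"paired test needs n >= 3, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    return ComparisonResult(
        label, n, a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
        float(t), float(df), float(p), "paired", corr,
    )


def independent_compare(g1, g2, kind: str = "pooled", label: str = "") -> ComparisonResult:
    """Two-sample t-test, classical pooled-variance or Welch."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("each group needs n >= 2")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if g1.mean() == g2.mean():
            raise DegenerateDataError("both groups constant and equal")
        raise DegenerateDataError("zero variance in both groups")
    if kind == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif kind == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (g1.mean() - g2.mean()) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        label, n1 + n2, g1.mean(), g1.std(ddof=1), g2.mean(), g2.std(ddof=1),
        float(t), float(df), float(p), f"independent-{kind}",
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (emitted as a marked extension)."""
    p = np.asarray(pvals, dtype=float)
    m = np.sum(~np.isnan(p))
    order = np.argsort(np.where(np.isnan(p), np.inf, p))
    adj = np.full_like(p, np.nan)
    running = 0.0
    rank = 0
    for i in order:
        if np.isnan(p[i]):
            continue
        rank += 1
        running = max(running, (m - rank + 1) * p[i])
        adj[i] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# cohort summaries (report shapes)
# ---------------------------------------------------------------------------


def _endpoint_values(records: list[CohortRecord], which: str) -> pd.DataFrame:
    rows = []
    for r in records:
        m = (r.planned if which == "planned" else r.delivered).as_dict()
        rows.append(
            {
                "patient_id": r.patient_id,
                "side": r.side,
                "xerostomia": r.xerostomia,
                **{e: m[e] for e in ENDPOINTS},
            }
        )
    return pd.DataFrame(rows)


def _fmt_pm(mean: float, sd: float) -> str:
    return f"{mean:.1f} ± {sd:.2f}"


def paired_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Planning-vs-delivered table over all glands (one row per endpoint)."""
    if len(records) < 3:
        raise SampleSizeError("paired table needs at least 3 glands")
    plan = _endpoint_values(records, "planned")
    deliv = _endpoint_values(records, "delivered")
    rows = []
    for e in ENDPOINTS:
        a, b = plan[e].to_numpy(), deliv[e].to_numpy()
        try:
            res = paired_compare(b, a, label=e)  # delivered minus planned
            t, df, p, corr = res.t, res.df, res.p, res.correlation
            note = ""
        except DegenerateDataError:
            t = df = p = corr = np.nan
            note = "degenerate: zero-variance differences"
        rows.append(
            {
                "parameter": e,
                "n_glands": len(records),
                "planning_mean": a.mean(),
                "planning_sd": a.std(ddof=1),
                "delivery_mean": b.mean(),
                "delivery_sd": b.std(ddof=1),
                "delta_mean": (b - a).mean(),
                "correlation": corr,
                "t": t,
                "df": df,
                "p": p,
                "note": note,
            }
        )
    df_out = pd.DataFrame(rows)
    df_out["p_holm_extension"] = holm_adjust(df_out["p"])
    return df_out


def _patient_level(values: pd.DataFrame) -> pd.DataFrame:
    """Average a patient's gland endpoints (the group-analysis unit)."""
    return values.groupby(["patient_id", "xerostomia"], as_index=False)[
        list(ENDPOINTS)
    ].mean()


def group_table(
    records: list[CohortRecord],
    which: str,
    alpha: float = 0.05,
    unit: str = "patient",
) -> pd.DataFrame:
    """Xerostomia vs no-xerostomia comparison for one dose type.

    ``unit='patient'`` (default) averages each patient's glands before
    comparing groups; ``unit='gland'`` compares glands directly.  D50 and
    Dmean rows carry the parotid tolerance references (30 and 26 Gy) and a
    flag when a group's mean exceeds its reference.
    """
    values = _endpoint_values(records, which)
    if unit == "patient":
        values = _patient_level(values)
    g_x = values[values["xerostomia"]]
    g_n = values[~values["xerostomia"]]
    if len(g_x) == 0 or len(g_n) == 0:
        raise GroupingError("both xerostomia groups must be nonempty")
    rows = []
    for e in ENDPOINTS:
        ref = TOLERANCE_REF.get(e, np.nan)
        mean_x, mean_n = float(g_x[e].mean()), float(g_n[e].mean())
        row = {
            "parameter": e,
            "ref_gy": ref,
            "xerostomia_mean": mean_x,
            "xerostomia_sd": float(g_x[e].std(ddof=1)),
            "no_xerostomia_mean": mean_n,
            "no_xerostomia_sd": float(g_n[e].std(ddof=1)),
            "xerostomia_above_ref": bool(mean_x > ref) if np.isfinite(ref) else pd.NA,
            "no_xerostomia_above_ref": bool(mean_n > ref) if np.isfinite(ref) else pd.NA,
            "note": "",
        }
        try:
            pooled = independent_compare(g_x[e], g_n[e], "pooled", label=e)
            welch = independent_compare(g_x[e], g_n[e], "welch", label=e)
            row.update(
                t=pooled.t, p=pooled.p, significant=pooled.p < alpha,
                p_welch=welch.p, df_welch=welch.df,
            )
        except DegenerateDataError:
            row.update(
                t=np.nan, p=np.nan, significant=False,
                p_welch=np.nan, df_welch=np.nan,
                note="degenerate: zero variance in both groups",
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_holm_extension"] = holm_adjust(out["p"])
    return out


def volume_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Pre/post gland volumes and per-gland relative change, by group."""
    rows = []
    df = pd.DataFrame(
        {
            "xerostomia": [r.xerostomia for r in records],
            "pre": [r.pre_volume_cc for r in records],
            "post": [r.post_volume_cc for r in records],
        }
    )
    df["rel_change_pct"] = 100.0 * (df["pre"] - df["post"]) / df["pre"]
    for label, sub in (
        ("xerostomia", df[df["xerostomia"]]),
        ("no_xerostomia", df[~df["xerostomia"]]),
    ):
        if len(sub) == 0:
            raise GroupingError(f"empty group {label}")
        rows.append(
            {
                "group": label,
                "n_glands": len(sub),
                "pre_mean_cc": sub["pre"].mean(),
                "pre_sd_cc": sub["pre"].std(ddof=1),
                "post_mean_cc": sub["post"].mean(),
                "post_sd_cc": sub["post"].std(ddof=1),
                # mean of per-gland relative changes, NOT change of means
                "volumetric_change_pct_mean": sub["rel_change_pct"].mean(),
                "volumetric_change_pct_sd": sub["rel_change_pct"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def change_summary(records: list[CohortRecord]) -> pd.DataFrame:
    """Both relative-change conventions, labelled distinctly.

    A percentage increase can mean the mean of each gland's own relative
    change or the relative change of the cohort means; these differ, so
    both are reported.
    """
    plan = _endpoint_values(records, "planned")
    deliv = _endpoint_values(records, "delivered")
    rows = []
    for e in ENDPOINTS:
        a, b = plan[e].to_numpy(), deliv[e].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            per_gland = 100.0 * (b - a) / a
        per_gland = per_gland[np.isfinite(per_gland)]
        mean_a = a.mean()
        rows.append(
            {
                "parameter": e,
                "mean_of_per_gland_change_pct": per_gland.mean()
                if per_gland.size
                else np.nan,
                "change_of_means_pct": 100.0 * (b.mean() - mean_a) / mean_a
                if mean_a != 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    records: list[CohortRecord], alpha: float = 0.05, unit: str = "patient"
) -> dict[str, pd.DataFrame]:
    """All report tables: paired, per-group planned/delivered, volumes, changes."""
    return {
        "paired": paired_table(records),
        "planned_by_group": group_table(records, "planned", alpha, unit),
        "delivered_by_group": group_table(records, "delivered", alpha, unit),
        "volume": volume_table(records),
        "change_summary": change_summary(records),
    }


def report_markdown(tables: dict[str, pd.DataFrame]) -> str:
    """Render the summary tables as a markdown report."""
    titles = {
        "paired": "Planning vs delivered dose (paired t-test, all glands)",
        "planned_by_group": "Planning dose by xerostomia group",
        "delivered_by_group": "Delivered dose by xerostomia group",
        "volume": "Parotid gland volume change",
        "change_summary": "Relative change summaries (both conventions)",
    }
    parts = []
    for key, df in tables.items():
        parts.append(f"## {titles.get(key, key)}\n")
        parts.append("```\n" + df.round(3).to_string(index=False) + "\n```")
        parts.append("")
    return "\n".join(parts)
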