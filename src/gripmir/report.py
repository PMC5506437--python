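"""Descriptive reporting: cohort summary, age trend of grip, result tables.

Every number shown in the rendered report is recomputed from the stage
output files in the run directory; nothing is carried over from in-memory
state, so the report can be regenerated at any time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_cohort

__all__ = ["AgeTrend", "fit_age_trend", "cohort_summary", "render_report", "collapse_grip_trials"]

logger = logging.getLogger("gripmir")


def collapse_grip_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Reduce long-format dynamometer trials to one maximum per participant.

    Expects columns ``participant_id`` and ``grip_kg`` (several rows per
    participant, e.g. three trials per hand); keeps the maximum.
    """
    if not {"participant_id", "grip_kg"} <= set(trials.columns):
        raise KeyError("trials table needs participant_id and grip_kg columns")
    return (
        trials.groupby("participant_id", as_index=False)["grip_kg"].max()
    )


@dataclass
class AgeTrend:
    """Per-sex quadratic age fit of grip plus 5-year-bin means."""

    coefficients: pd.DataFrame  # rows: sex; cols: intercept, age, age2
    bins: pd.DataFrame  # sex, age_lo, age_hi, n, mean, se


def fit_age_trend(cohort: pd.DataFrame, bin_width: float = 5.0) -> AgeTrend:
    """OLS of grip on age and age^2 within each sex, plus binned means.

    Age is centred at the cohort mean before fitting, so ``intercept`` is
    the expected grip at mean age and ``age`` is the decline rate (kg/year)
    at mean age rather than an extrapolated value at age 0.  A sex stratum
    with fewer than three distinct ages cannot identify the quadratic; the
    quadratic term is then dropped (reported as 0).
    """
    if not {"grip_kg", "age", "sex"} <= set(cohort.columns):
        raise KeyError("cohort needs sex, age and grip_kg columns")
    coef_rows = []
    bin_rows = []
    age_centre = float(cohort["age"].mean())
    lo = np.floor(cohort["age"].min() / bin_width) * bin_width
    hi = np.ceil(cohort["age"].max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    for sex, sub in cohort.groupby("sex"):
        age = sub["age"].to_numpy(dtype=float) - age_centre
        grip = sub["grip_kg"].to_numpy(dtype=float)
        distinct = np.unique(age).size
        if np.ptp(grip) == 0.0:
            c0, c1, c2 = float(grip[0]), 0.0, 0.0
        elif distinct >= 3:
            c2, c1, c0 = np.polyfit(age, grip, 2)
        elif distinct == 2:
            logger.warning("sex %s: <3 distinct ages; quadratic term skipped", sex)
            c1, c0 = np.polyfit(age, grip, 1)
            c2 = 0.0
        else:
            logger.warning("sex %s: constant age; age trend skipped", sex)
            c0, c1, c2 = float(np.mean(grip)), 0.0, 0.0
        age = sub["age"].to_numpy(dtype=float)  # raw age for binning
        coef_rows.append({"sex": sex, "intercept": float(c0), "age": float(c1), "age2": float(c2)})
        which = np.digitize(age, edges[1:-1], right=False)
        for b in range(len(edges) - 1):
            m = which == b
            if not m.any():
                continue
            vals = grip[m]
            bin_rows.append(
                {
                    "sex": sex,
                    "age_lo": float(edges[b]),
                    "age_hi": float(edges[b + 1]),
                    "n": int(m.sum()),
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(m.sum())) if m.sum() > 1 else np.nan,
                }
            )
    return AgeTrend(pd.DataFrame(coef_rows), pd.DataFrame(bin_rows))


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of the main characteristics, overall and by sex."""
    numeric = [
        ("Age, years", "age"),
        ("Grip strength, kg", "grip_kg"),
        ("Height, inches", "height_in"),
        ("BMI, kg m^-2", "bmi"),
    ]
    frames = {"Overall": cohort, "Men": cohort[cohort["sex"] == "M"], "Women": cohort[cohort["sex"] == "F"]}
    rows = []
    for label, col in numeric:
        if col not in cohort.columns:
            continue
        row = {"Characteristic": label}
        for name, sub in frames.items():
            row[f"{name} (N={len(sub)})"] = f"{sub[col].mean():.1f} ({sub[col].std(ddof=1):.1f})"
        rows.append(row)
    pct = {"Characteristic": "Women, %"}
    for name, sub in frames.items():
        pct[f"{name} (N={len(sub)})"] = (
            f"{100.0 * (sub['sex'] == 'F').mean():.0f}" if name == "Overall" else "-"
        )
    rows.append(pct)
    return pd.DataFrame(rows)


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return "" if np.isnan(v) else floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join([" --- "] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def _threshold_sentence(summary: pd.DataFrame) -> str:
    parts = []
    for row in summary.itertuples(index=False):
        parts.append(f"{row.count} ({row.percent:.0f}%) had FDR q value < {row.threshold:g}")
    total = int(summary["total"].iloc[0]) if len(summary) else 0
    return f"Among {total} miRNAs interrogated, " + ", ".join(parts) + "."


def render_report(run_dir: str | Path, k_top: int = 15) -> str:
    """Assemble the Markdown summary from a run directory's artifacts.

    Sections whose inputs are missing are replaced by a short notice rather
    than failing, so partial runs still render.
    """
    run_dir = Path(run_dir)
    lines: list[str] = ["# Grip strength / miRNA pipeline report", ""]

    cohort_path = run_dir / "cohort.tsv"
    if cohort_path.exists():
        cohort = read_cohort(cohort_path)
        lines += ["## Cohort characteristics", "", _md_table(cohort_summary(cohort)), ""]
        if "grip_kg" in cohort.columns:
            trend = fit_age_trend(cohort)
            lines += [
                "## Grip strength by age",
                "",
                "Quadratic age fit per sex (grip = intercept + b1*(age-mean) + b2*(age-mean)^2):",
                "",
                _md_table(trend.coefficients, floatfmt="{:.5g}"),
                "",
                "5-year age-bin means (kg):",
                "",
                _md_table(trend.bins),
                "",
            ]
    else:
        lines += ["## Cohort characteristics", "", "_cohort.tsv missing; section omitted_", ""]

    assoc_path = run_dir / "association.tsv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path, sep="\t")
        eligible = assoc[assoc["branch"] != "ineligible"].dropna(subset=["adaptive_p"])
        lines += ["## miRNA associations with grip strength", ""]
        if len(eligible) == 0:
            lines += ["No eligible miRNAs.", ""]
        else:
            from .multiple_testing import threshold_summary

            summary = threshold_summary(eligible["fdr_q"].to_numpy())
            lines += [_threshold_sentence(summary), ""]
            top = eligible.nsmallest(k_top, ["fdr_q", "adaptive_p"])[
                ["mirna", "n", "beta_cont", "se_cont", "p_cont",
                 "beta_bin", "se_bin", "p_bin", "branch", "adaptive_p", "fdr_q"]
            ]
            lines += [f"Top {len(top)} miRNAs:", "", _md_table(top), ""]
    else:
        lines += ["## miRNA associations with grip strength", "", "_association.tsv missing; section omitted_", ""]

    calib_path = run_dir / "calibration.json"
    if calib_path.exists():
        calib = json.loads(calib_path.read_text())
        lines += [
            "## Permutation calibration",
            "",
            f"{calib['n_replicates']} permutation replicates, "
            f"{calib['n_tests_total']} pooled null tests: "
            f"fraction of adaptive p < 0.05 = {calib['frac_below_05']:.4f}, "
            f"< 0.01 = {calib['frac_below_01']:.4f}; "
            f"KS vs Uniform(0,1) = {calib['ks_statistic']:.4f} "
            f"(p = {calib['ks_pvalue']:.3g}).",
            "",
        ]

    pairs_path = run_dir / "coexpression_pairs.tsv"
    if pairs_path.exists():
        pairs = pd.read_csv(pairs_path, sep="\t")
        sig = pairs[pairs["significant"]]
        lines += [
            "## miRNA-mRNA coexpression",
            "",
            f"{len(sig)} significant pairs (FDR < 0.05) over {len(pairs)} tested; "
            f"{int(sig['predicted_target'].sum())} of the significant pairs are "
            f"predicted targets; {sig['gene'].nunique()} unique genes.",
            "",
        ]

    enrich_path = run_dir / "enrichment.tsv"
    if enrich_path.exists():
        enrich = pd.read_csv(enrich_path, sep="\t")
        lines += ["## Gene-set enrichment", "", _md_table(enrich.head(10), floatfmt="{:.3g}"), ""]
    else:
        lines += ["## Gene-set enrichment", "", "_enrichment.tsv missing; section omitted_", ""]

    return "\n".join(lines)
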