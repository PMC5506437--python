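"""FDR control and permutation calibration of the adaptive test.

q-values use the Benjamini-Hochberg step-up procedure (via statsmodels).
The permutation scheme separates the miRNA matrix from the clinical block
(grip, covariates and family ID travel together under one shared
permutation), so covariate-phenotype structure is preserved while every
miRNA-phenotype link is broken; re-running the full two-part analysis on
permuted replicates yields the empirical null distribution of adaptive
p-values and hence a direct type-I-error check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CqMatrix

__all__ = [
    "PermutationPlan",
    "CalibrationReport",
    "bh_fdr",
    "attach_fdr",
    "threshold_summary",
    "permute_clinical",
    "permutation_calibration",
]

logger = logging.getLogger("gripmir")

#: q-value thresholds reported by summaries, descending
DEFAULT_THRESHOLDS = (0.10, 0.05, 0.01, 0.001)


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped at 1 — the literal step-up definition, evaluated exactly in that
    form.  All p must lie in (0, 1]; an empty vector returns an empty one.
    (statsmodels' ``fdr_bh`` agrees to floating-point reordering; it is used
    as a cross-check in the test suite.)
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def attach_fdr(results: list) -> None:
    """Fill ``q`` on association results in place, over eligible miRNAs."""
    idx = [i for i, r in enumerate(results) if r.adaptive_p is not None]
    if not idx:
        return
    q = bh_fdr([results[i].adaptive_p for i in idx])
    for j, i in enumerate(idx):
        results[i].q = float(q[j])


def threshold_summary(
    qvalues: np.ndarray | list[float],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Counts and percentages below each q threshold (strict ``<``)."""
    q = np.asarray(qvalues, dtype=float)
    q = q[~np.isnan(q)]
    total = q.size
    rows = []
    for t in thresholds:
        k = int((q < t).sum())
        rows.append(
            {
                "threshold": t,
                "count": k,
                "total": total,
                "percent": 0.0 if total == 0 else 100.0 * k / total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PermutationPlan:
    """How to permute: number of replicates and the clinical block columns.

    ``permuted_block`` of None means every cohort column except
    participant_id — grip, covariates and family ID move as one unit.
    """

    n_replicates: int = 100
    seed: int = 0
    permuted_block: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def permute_clinical(
    cohort: pd.DataFrame,
    seed: int | np.random.Generator,
    block: list[str] | None = None,
) -> pd.DataFrame:
    """Reorder the clinical block by one shared random permutation.

    participant_id (and any column outside the block) keeps its original
    order, so row i of the returned table pairs participant i's miRNA data
    with a random participant's phenotype and family assignment.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if block is None:
        block = [c for c in cohort.columns if c != "participant_id"]
    missing = [c for c in block if c not in cohort.columns]
    if missing:
        raise KeyError(f"permuted columns absent from cohort: {missing}")
    perm = rng.permutation(len(cohort))
    out = cohort.copy()
    for col in block:  # per column, so dtypes survive the reordering
        out[col] = cohort[col].to_numpy()[perm]
    return out


@dataclass
class CalibrationReport:
    """Pooled and per-replicate summary of the permutation null."""

    n_replicates: int
    n_tests_total: int
    frac_below_05: float
    frac_below_01: float
    ks_statistic: float
    ks_pvalue: float
    replicates: pd.DataFrame = field(repr=False)
    pooled_p: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_tests_total": self.n_tests_total,
            "frac_below_05": self.frac_below_05,
            "frac_below_01": self.frac_below_01,
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "replicates": self.replicates.to_dict(orient="records"),
        }


def permutation_calibration(
    cohort: pd.DataFrame,
    cq: CqMatrix,
    covariates: list[str],
    plan: PermutationPlan,
    options=None,
) -> CalibrationReport:
    """Empirical type-I-error check of the adaptive test.

    Each replicate permutes the clinical block, reruns the full two-part
    analysis, and pools the resulting adaptive p-values, which are uniform
    on (0, 1) when the test's size is correct even though the original
    cohort may carry strong true effects.  Replicates that fail are logged
    and skipped; more than 10% failures aborts.
    """
    from .association import AssociationOptions, associate_all

    opt = options or AssociationOptions(attach_q=False)
    opt.attach_q = False
    rng = np.random.default_rng(plan.seed)
    pooled: list[np.ndarray] = []
    rows = []
    failures = 0
    for rep in range(plan.n_replicates):
        try:
            permuted = permute_clinical(cohort, rng, plan.permuted_block)
            results = associate_all(permuted, cq, covariates, opt)
            pvals = np.array(
                [r.adaptive_p for r in results if r.adaptive_p is not None]
            )
        except Exception as exc:  # noqa: BLE001 - a replicate must not kill the run
            failures += 1
            logger.warning("permutation replicate %d failed: %s", rep, exc)
            continue
        pooled.append(pvals)
        rows.append(
            {
                "replicate": rep,
                "n_tests": pvals.size,
                "frac_below_05": float((pvals < 0.05).mean()) if pvals.size else np.nan,
                "min_p": float(pvals.min()) if pvals.size else np.nan,
            }
        )
    if failures > 0.10 * plan.n_replicates:
        raise RuntimeError(
            f"{failures}/{plan.n_replicates} permutation replicates failed"
        )
    allp = np.concatenate(pooled) if pooled else np.array([])
    if allp.size:
        ks = stats.kstest(allp, "uniform")
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    return CalibrationReport(
        n_replicates=len(rows),
        n_tests_total=int(allp.size),
        frac_below_05=float((allp < 0.05).mean()) if allp.size else np.nan,
        frac_below_01=float((allp < 0.01).mean()) if allp.size else np.nan,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        replicates=pd.DataFrame(rows),
        pooled_p=allp,
    )
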