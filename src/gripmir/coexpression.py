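"""miRNA-mRNA coexpression selection and gene-set over-representation.

For a short list of grip-associated miRNAs, every profiled gene is regressed
on the miRNA's detected Cq (covariate-adjusted, family random intercept);
pairs significant at FDR < 0.05 are annotated against a target-prediction
table and gene signatures, and the unique genes they involve are tested for
over-representation in gene sets with a one-sided hypergeometric test.  The
"ratio of enrichment" for a set is the observed overlap divided by the
overlap expected if the selected genes were drawn uniformly from the
universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult, _design, _try_fit
from .io import CqMatrix
from .lmm import ModelFit
from .multiple_testing import bh_fdr

__all__ = [
    "CoexpressionPair",
    "EnrichmentResult",
    "select_top_mirnas",
    "select_negative_direction",
    "coexpress_pairs",
    "pairs_to_frame",
    "targetscan_overlap",
    "signature_overlap",
    "hypergeom_enrich",
    "enrich_custom_pathways",
    "enrichment_to_frame",
]

logger = logging.getLogger("gripmir")


@dataclass
class CoexpressionPair:
    mirna: str
    gene: str
    beta: float  # expression units per Cq
    se: float
    p: float
    q: float | None = None
    predicted_target: bool = False

    @property
    def significant(self) -> bool:
        return self.q is not None and self.q < 0.05


@dataclass
class EnrichmentResult:
    set_name: str
    genes_in_overlap: int
    ratio_of_enrichment: float
    p: float
    q: float | None = None


def select_top_mirnas(results: list[AssociationResult], k: int) -> list[str]:
    """The k miRNAs with smallest FDR q (ties: adaptive p, then name)."""
    scored = [
        (r.q, r.adaptive_p, r.mirna)
        for r in results
        if r.q is not None and r.adaptive_p is not None
    ]
    scored.sort()
    if k > len(scored):
        logger.warning("requested top %d miRNAs but only %d available", k, len(scored))
    return [m for _, _, m in scored[:k]]


def select_negative_direction(
    results: list[AssociationResult], q_cutoff: float = 0.05
) -> list[str]:
    """Significant miRNAs whose expression is negatively associated with grip.

    On the Cq scale that means a strictly positive governing beta (higher
    Cq, i.e. lower expression, predicting higher grip).
    """
    out = []
    for r in results:
        if r.q is None or not r.q < q_cutoff:
            continue
        beta = r.governing_beta
        if beta is not None and beta > 0:
            out.append(r.mirna)
    return sorted(out)


def coexpress_pairs(
    cq: CqMatrix,
    mrna: pd.DataFrame,
    mirnas: list[str],
    covariates: list[str],
    cohort: pd.DataFrame,
    grouping: str = "family_id",
    q_cutoff: float = 0.05,
) -> list[CoexpressionPair]:
    """Pairwise mixed-model coexpression for the given miRNAs vs all genes.

    Each fit regresses a gene's expression on centred detected Cq with the
    same covariates and family random intercept as the grip models; q-values
    are computed across all pairs of this run.  Zero-variance genes are
    skipped with a log entry.
    """
    if not cq.values.index.equals(mrna.index):
        raise ValueError("Cq and mRNA matrices are not row-aligned")
    if len(cohort) != len(mrna):
        raise ValueError("cohort and expression tables differ in length")
    pairs: list[CoexpressionPair] = []
    groups_all = cohort[grouping].to_numpy()
    expr = mrna.to_numpy(dtype=float)
    gene_names = list(mrna.columns)
    for mirna in mirnas:
        if mirna not in cq.values.columns:
            logger.warning("%s absent from the Cq matrix; skipped", mirna)
            continue
        col = cq.values[mirna].to_numpy()
        det = np.isfinite(col) & (col <= cq.threshold)
        if det.sum() < 10:
            logger.warning("%s detected in only %d samples; skipped", mirna, det.sum())
            continue
        sub = cohort.loc[det]
        focal = col[det] - col[det].mean()
        X = _design(sub, covariates, focal)
        g = groups_all[det]
        sub_expr = expr[det]
        for j, gene in enumerate(gene_names):
            y = sub_expr[:, j]
            if np.ptp(y) == 0.0:
                logger.info("%s ~ %s skipped: zero gene variance", gene, mirna)
                continue
            fit: ModelFit | None = _try_fit(y, X, g, mirna, f"coexpression:{gene}")
            if fit is None or not fit.converged:
                continue
            pairs.append(CoexpressionPair(mirna, gene, fit.beta, fit.se, fit.p))
    if pairs:
        q = bh_fdr([p.p for p in pairs])
        for pair, qi in zip(pairs, q):
            pair.q = float(qi)
    return pairs


def pairs_to_frame(pairs: list[CoexpressionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [p.mirna for p in pairs],
            "gene": [p.gene for p in pairs],
            "beta": [p.beta for p in pairs],
            "se": [p.se for p in pairs],
            "p": [p.p for p in pairs],
            "q": [np.nan if p.q is None else p.q for p in pairs],
            "predicted_target": [p.predicted_target for p in pairs],
            "significant": [p.significant for p in pairs],
        }
    )


def targetscan_overlap(
    pairs: list[CoexpressionPair], prediction_table: pd.DataFrame
) -> int:
    """Flag predicted pairs in place; return the count of significant ones."""
    predicted = set()
    skipped = 0
    for row in prediction_table.itertuples(index=False):
        try:
            predicted.add((str(row.mirna), str(row.gene)))
        except AttributeError:
            skipped += 1
    if skipped:
        logger.warning("%d malformed prediction rows skipped", skipped)
    count = 0
    for p in pairs:
        p.predicted_target = (p.mirna, p.gene) in predicted
        if p.predicted_target and p.significant:
            count += 1
    return count


def signature_overlap(
    pairs: list[CoexpressionPair], signature: list[str]
) -> tuple[list[CoexpressionPair], int]:
    """Significant pairs whose gene sits in the signature, and the number of
    unique genes among them."""
    if not signature:
        raise ValueError("signature gene list is empty")
    sig = set(signature)
    hits = [p for p in pairs if p.significant and p.gene in sig]
    return hits, len({p.gene for p in hits})


def hypergeom_enrich(
    selected_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation across gene sets.

    Selected genes outside the universe are dropped with a warning and each
    set is intersected with the universe first.  For a universe of size N, a
    set of size K and n selected genes with overlap k:

        ratio_of_enrichment = k / (n * K / N)
        p = P[X >= k],  X ~ Hypergeometric(N, K, n)

    q-values are BH across the reported sets; results sorted by p.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty gene universe")
    uniset = set(uni)
    sel = list(dict.fromkeys(selected_genes))
    outside = [g for g in sel if g not in uniset]
    if outside:
        logger.warning("%d selected genes outside the universe dropped", len(outside))
        sel = [g for g in sel if g in uniset]
    n_sel, N = len(sel), len(uni)
    selset = set(sel)
    results: list[EnrichmentResult] = []
    for name, genes in gene_sets.items():
        members = set(genes) & uniset
        if not members:
            logger.warning("gene set %s lies fully outside the universe; skipped", name)
            continue
        K = len(members)
        k = len(selset & members)
        expected = n_sel * K / N
        ratio = 0.0 if expected == 0 else k / expected
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sel))
        results.append(EnrichmentResult(name, k, ratio, min(p, 1.0)))
    if results:
        q = bh_fdr([max(r.p, np.finfo(float).tiny) for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrich_custom_pathways(
    selected_genes: list[str],
    pathways: dict[str, list[str]],
    universe: list[str],
) -> list[EnrichmentResult]:
    """Same machinery as :func:`hypergeom_enrich` on user-supplied lists
    (e.g. insulin-signaling-like, mTOR-like or aging-gene collections)."""
    deduped = {name: list(dict.fromkeys(genes)) for name, genes in pathways.items()}
    return hypergeom_enrich(selected_genes, deduped, universe)


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "genes_in_overlap": [r.genes_in_overlap for r in results],
            "ratio_of_enrichment": [r.ratio_of_enrichment for r in results],
            "p": [r.p for r in results],
            "q": [np.nan if r.q is None else r.q for r in results],
        }
    )
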