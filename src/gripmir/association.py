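"""Two-part (hurdle) mixed-model association of censored Cq values with grip.

qPCR panels leave many miRNAs undetected in many participants: the Cq value
is censored at the instrument's detection limit.  A single regression on Cq
would either drop the undetected majority or impute it arbitrarily, so each
miRNA is tested with two linear mixed models (family random intercept):

* model 1 (everyone assayed):  grip ~ X + covariates, where X = 1 if the
  miRNA is undetected (Cq beyond the limit), 0 if detected;
* model 2 (detected subset):   grip ~ Cq + covariates.

An adaptive rule routes each miRNA by its detected fraction: below 10%
model 1 alone is used, at or above 90% model 2 alone, and in between the two
Wald chi-square statistics are summed and referred to a chi-square
distribution with 2 degrees of freedom.  miRNAs detected in fewer than 5% of
the full cohort are ineligible and skipped.

Because higher Cq means lower expression, a negative beta on Cq (or on the
undetected indicator) denotes a positive association between miRNA
expression and grip strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .io import CqMatrix
from .lmm import ModelFit, RankDeficientError, fit_lmm

__all__ = [
    "Branch",
    "DetectionProfile",
    "AssociationResult",
    "EmptyDataError",
    "binary_indicator",
    "classify_branch",
    "adaptive_p",
    "associate_all",
    "sex_stratified",
    "impute_cell_counts",
    "results_to_frame",
]

logger = logging.getLogger("gripmir")

#: branching cutoffs on the detected fraction
LOWER_CUTOFF = 0.10
UPPER_CUTOFF = 0.90
#: eligibility floor as a fraction of the full cohort
ELIGIBILITY_FRACTION = 0.05

# minimum rows for attempting the continuous (detected-subset) model
_MIN_CONTINUOUS_N = 30


class EmptyDataError(ValueError):
    """No usable observations remain after masking."""


class Branch(str, Enum):
    INELIGIBLE = "ineligible"
    BINARY_ONLY = "binary_only"
    COMBINED = "combined"
    CONTINUOUS_ONLY = "continuous_only"


@dataclass
class DetectionProfile:
    mirna: str
    n_assayed: int
    n_detected: int
    detected_fraction: float
    branch: Branch


@dataclass
class AssociationResult:
    mirna: str
    profile: DetectionProfile
    fit_binary: ModelFit | None
    fit_continuous: ModelFit | None
    adaptive_p: float | None
    q: float | None = None

    @property
    def governing_beta(self) -> float | None:
        """The effect estimate the branch rests on: continuous when that model
        was fitted and converged, otherwise the binary one."""
        if self.fit_continuous is not None and self.fit_continuous.converged:
            return self.fit_continuous.beta
        if self.fit_binary is not None and self.fit_binary.converged:
            return self.fit_binary.beta
        return None


def binary_indicator(cq_column: pd.Series | np.ndarray, threshold: float) -> pd.Series:
    """Undetected indicator X: 1 if Cq > threshold (or censored), 0 if detected.

    Not-assayed entries (NaN) stay NaN and are excluded from model 1.  The
    boundary is strict: Cq exactly at the threshold counts as detected.
    """
    if threshold <= 0:
        raise ValueError("detection threshold must be positive")
    s = pd.Series(np.asarray(cq_column, dtype=float))
    if isinstance(cq_column, pd.Series):
        s.index = cq_column.index
    if s.notna().sum() == 0:
        raise EmptyDataError("all entries are not-assayed")
    x = pd.Series(np.nan, index=s.index, dtype=float)
    finite = np.isfinite(s.to_numpy())
    x[finite & (s > threshold)] = 1.0
    x[np.isposinf(s.to_numpy())] = 1.0
    x[finite & (s <= threshold)] = 0.0
    return x


def classify_branch(
    mirna: str,
    n_assayed: int,
    n_detected: int,
    eligibility_floor: int,
    lower: float = LOWER_CUTOFF,
    upper: float = UPPER_CUTOFF,
) -> DetectionProfile:
    """Route a miRNA by its detection profile.

    ``eligibility_floor`` is an absolute detected-sample count (normally 5%
    of the full cohort).  The upper boundary is inclusive: a miRNA detected
    in exactly 90% of assayed samples uses the continuous model alone.
    """
    if n_assayed < 1:
        raise ValueError("n_assayed must be >= 1")
    frac = n_detected / n_assayed
    if n_detected < eligibility_floor:
        branch = Branch.INELIGIBLE
    elif frac < lower:
        branch = Branch.BINARY_ONLY
    elif frac >= upper:
        branch = Branch.CONTINUOUS_ONLY
    else:
        branch = Branch.COMBINED
    return DetectionProfile(mirna, n_assayed, n_detected, frac, branch)


def adaptive_p(
    p_binary: float | None,
    p_continuous: float | None,
    branch: Branch,
) -> float:
    """Combine the two models' p-values according to the branch.

    For the combined branch each p is inverted through the chi-square(1)
    upper tail to recover its Wald statistic; the statistics are summed and
    referred to chi-square(2).  Single-model branches pass through.
    """
    for name, p in (("p_binary", p_binary), ("p_continuous", p_continuous)):
        if p is not None and not (0.0 < p <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {p}")
    if branch == Branch.BINARY_ONLY:
        if p_binary is None:
            raise ValueError("binary_only branch requires p_binary")
        return p_binary
    if branch == Branch.CONTINUOUS_ONLY:
        if p_continuous is None:
            raise ValueError("continuous_only branch requires p_continuous")
        return p_continuous
    if branch == Branch.COMBINED:
        if p_binary is None or p_continuous is None:
            raise ValueError("combined branch requires both p-values")
        x = float(stats.chi2.isf(p_binary, 1) + stats.chi2.isf(p_continuous, 1))
        return float(stats.chi2.sf(x, 2))
    raise ValueError(f"no adaptive p for branch {branch}")


def _design(
    cohort: pd.DataFrame, covariates: list[str], focal: np.ndarray
) -> np.ndarray:
    """Design matrix [focal, intercept, dummies+numeric covariates]."""
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"covariates absent from cohort table: {missing}")
    parts = [pd.Series(focal, index=cohort.index, name="_focal")]
    if covariates:
        enc = pd.get_dummies(cohort[covariates], drop_first=True, dtype=float)
        parts.append(enc)
    X = pd.concat(parts, axis=1)
    X.insert(1, "_const", 1.0)
    return X.to_numpy(dtype=float)


def _try_fit(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, mirna: str, label: str
) -> ModelFit | None:
    try:
        return fit_lmm(y, X, groups, focal=0)
    except (RankDeficientError, ValueError) as exc:
        logger.debug("%s: %s model not fitted (%s)", mirna, label, exc)
        return None


@dataclass
class AssociationOptions:
    response: str = "grip_kg"
    grouping: str = "family_id"
    lower_cutoff: float = LOWER_CUTOFF
    upper_cutoff: float = UPPER_CUTOFF
    eligibility_fraction: float = ELIGIBILITY_FRACTION
    min_continuous_n: int = _MIN_CONTINUOUS_N
    attach_q: bool = True


def associate_all(
    cohort: pd.DataFrame,
    cq: CqMatrix,
    covariates: list[str],
    options: AssociationOptions | None = None,
) -> list[AssociationResult]:
    """Run the two-part adaptive test for every miRNA in the matrix.

    Both models are fitted whenever the data allow (mirroring reports that
    tabulate both regardless of branch); the adaptive p follows the branch.
    Results are ordered by miRNA name; ineligible miRNAs are retained with
    no p-value so callers can report why they were skipped.  FDR q-values
    are attached across the eligible miRNAs unless ``options.attach_q`` is
    off.
    """
    opt = options or AssociationOptions()
    if opt.response not in cohort.columns:
        raise KeyError(f"response column {opt.response!r} missing")
    n_cohort = len(cohort)
    floor = ceil(opt.eligibility_fraction * n_cohort)
    groups_all = cohort[opt.grouping].to_numpy()
    y_all = cohort[opt.response].to_numpy(dtype=float)

    results: list[AssociationResult] = []
    for mirna in sorted(cq.values.columns):
        col = cq.values[mirna].to_numpy()
        assayed = ~np.isnan(col)
        n_assayed = int(assayed.sum())
        if n_assayed == 0:
            logger.warning("%s: never assayed; skipped", mirna)
            continue
        detected = np.isfinite(col) & (col <= cq.threshold)
        profile = classify_branch(
            mirna, n_assayed, int(detected.sum()), floor,
            lower=opt.lower_cutoff, upper=opt.upper_cutoff,
        )
        if profile.branch == Branch.INELIGIBLE:
            results.append(AssociationResult(mirna, profile, None, None, None))
            continue

        sub = cohort.loc[assayed]
        indicator = np.where(detected[assayed], 0.0, 1.0)
        fit_bin: ModelFit | None = None
        if 0.0 < indicator.mean() < 1.0:
            Xb = _design(sub, covariates, indicator)
            fit_bin = _try_fit(y_all[assayed], Xb, groups_all[assayed], mirna, "binary")

        fit_cont: ModelFit | None = None
        if detected.sum() >= opt.min_continuous_n:
            subd = cohort.loc[detected]
            cq_det = col[detected]
            Xc = _design(subd, covariates, cq_det - cq_det.mean())
            fit_cont = _try_fit(
                y_all[detected], Xc, groups_all[detected], mirna, "continuous"
            )

        p_bin = fit_bin.p if fit_bin is not None and fit_bin.converged else None
        p_cont = fit_cont.p if fit_cont is not None and fit_cont.converged else None
        branch = profile.branch
        try:
            ap: float | None = adaptive_p(p_bin, p_cont, branch)
        except ValueError:
            # combined branch with one component unavailable: fall back to
            # the model that did fit rather than dropping the miRNA
            avail = p_cont if p_cont is not None else p_bin
            if avail is None:
                logger.warning("%s: no model converged; excluded from FDR", mirna)
                ap = None
            else:
                logger.warning(
                    "%s: only one model available on the %s branch; using it",
                    mirna, branch.value,
                )
                ap = avail
        results.append(AssociationResult(mirna, profile, fit_bin, fit_cont, ap))

    if not any(r.adaptive_p is not None for r in results):
        logger.warning("no eligible miRNAs produced an adaptive p-value")
    if opt.attach_q:
        from .multiple_testing import attach_fdr

        attach_fdr(results)
    return results


def sex_stratified(
    cohort: pd.DataFrame,
    cq: CqMatrix,
    covariates: list[str],
    options: AssociationOptions | None = None,
    min_stratum: int = 50,
) -> dict[str, list[AssociationResult]]:
    """Per-sex association for miRNAs detected in >= 90% of assayed samples.

    ``covariates`` should not include sex; it is removed with a warning if
    present (a constant column would make the stratified design singular).
    """
    opt = options or AssociationOptions()
    covs = [c for c in covariates if c != "sex"]
    if covs != list(covariates):
        logger.warning("dropping 'sex' from stratified covariate list")
    summary = cq.detection_summary()
    keep = summary.index[summary["detected_fraction"] >= opt.upper_cutoff]
    cq_high = CqMatrix(cq.values[list(keep)], threshold=cq.threshold)

    out: dict[str, list[AssociationResult]] = {}
    for sex in ("M", "F"):
        mask = (cohort["sex"] == sex).to_numpy()
        if mask.sum() < min_stratum:
            logger.warning("sex stratum %s has %d participants; skipped", sex, mask.sum())
            out[sex] = []
            continue
        sub_cohort = cohort.loc[mask].reset_index(drop=True)
        # Cq rows are positionally aligned to cohort rows.
        sub_cq = CqMatrix(cq_high.values.iloc[np.flatnonzero(mask)], threshold=cq.threshold)
        out[sex] = associate_all(sub_cohort, sub_cq, covs, opt)
    return out


def impute_cell_counts(
    expression: pd.DataFrame,
    measured: pd.DataFrame,
    max_components: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete blood cell counts by partial least squares on expression.

    For each count variable, a PLS regression of the measured subset on the
    expression matrix is trained with the number of latent components chosen
    to minimise 10-fold cross-validated RMSE; predictions fill the unmeasured
    participants while measured values pass through unchanged.

    ``measured`` has a ``participant_id`` column plus one column per count
    variable, NaN where unmeasured; ``expression`` is indexed by
    participant_id and must cover every participant.
    """
    if "participant_id" not in measured.columns:
        raise KeyError("measured table needs a participant_id column")
    ids = measured["participant_id"]
    missing_expr = set(ids) - set(expression.index)
    if missing_expr:
        raise KeyError(f"expression missing for {len(missing_expr)} participants")
    X_all = expression.loc[ids].to_numpy(dtype=float)

    out = measured.copy()
    rng_seed = seed
    for var in [c for c in measured.columns if c != "participant_id"]:
        yv = measured[var].to_numpy(dtype=float)
        have = ~np.isnan(yv)
        if have.sum() == 0:
            raise EmptyDataError(f"no measured values for {var}")
        if have.all():
            continue
        X_train, y_train = X_all[have], yv[have]
        folds = n_folds
        if have.sum() < n_folds:
            folds = max(2, int(have.sum()))
            logger.warning("%s: only %d measured rows; using %d folds", var, have.sum(), folds)
        k_max = int(min(max_components, X_train.shape[1], have.sum() - ceil(have.sum() / folds) - 1))
        k_max = max(k_max, 1)
        best_k, best_rmse = 1, np.inf
        kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        splits = list(kf.split(X_train))
        for k in range(1, k_max + 1):
            sse, cnt = 0.0, 0
            for tr, te in splits:
                pls = PLSRegression(n_components=k, scale=False)
                pls.fit(X_train[tr], y_train[tr])
                pred = pls.predict(X_train[te]).ravel()
                sse += float(((pred - y_train[te]) ** 2).sum())
                cnt += len(te)
            rmse = np.sqrt(sse / cnt)
            if rmse < best_rmse - 1e-12:
                best_rmse, best_k = rmse, k
        pls = PLSRegression(n_components=best_k, scale=False)
        pls.fit(X_train, y_train)
        filled = yv.copy()
        filled[~have] = pls.predict(X_all[~have]).ravel()
        out[var] = filled
        logger.info("%s: PLS imputation with %d components (CV RMSE %.4g)", var, best_k, best_rmse)
    return out


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results into the output table (one row per miRNA)."""

    def _f(fit: ModelFit | None, attr: str) -> float:
        return getattr(fit, attr) if fit is not None else np.nan

    rows = []
    for r in results:
        rows.append(
            {
                "mirna": r.mirna,
                "n": r.profile.n_assayed,
                "n_detected": r.profile.n_detected,
                "detected_fraction": r.profile.detected_fraction,
                "beta_cont": _f(r.fit_continuous, "beta"),
                "se_cont": _f(r.fit_continuous, "se"),
                "p_cont": _f(r.fit_continuous, "p"),
                "beta_bin": _f(r.fit_binary, "beta"),
                "se_bin": _f(r.fit_binary, "se"),
                "p_bin": _f(r.fit_binary, "p"),
                "branch": r.profile.branch.value,
                "adaptive_p": np.nan if r.adaptive_p is None else r.adaptive_p,
                "fdr_q": np.nan if r.q is None else r.q,
            }
        )
    return pd.DataFrame(rows)
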