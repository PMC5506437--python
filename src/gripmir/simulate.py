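"""Synthetic family-cohort generator for the grip-strength / miRNA pipeline.

Individual-level cohort data of the kind this pipeline targets (family-based
epidemiological samples with whole-blood qPCR miRNA panels) are access
restricted, so every downstream stage is exercised on simulated cohorts.  The
generator emulates the features that matter to the statistics:

* covariate marginals of a middle-aged community sample (54% women, age
  ~N(55.7, 13.2) truncated to [24, 90], sex-specific height and BMI);
* sex-specific grip strength with a quadratic age decline, family-clustered
  random intercepts and sex-specific residual spread, calibrated so the
  sex-stratified means and SDs land near 44.7 (10.0) kg in men and
  26.5 (6.3) kg in women;
* per-miRNA Cq panels censored at a detection limit (default 27 cycles),
  with detection fractions spanning <5% to 100% and optional partial assay
  coverage (some miRNAs measured in only a subset of the cohort);
* planted miRNA -> grip effects on the Cq scale (continuous, e.g. -0.20 kg
  per Cq unit, and/or binary detected-vs-undetected shifts in kg);
* miRNA-correlated mRNA blocks plus independent null genes, for the
  coexpression and enrichment stages.

Covariates are drawn independently of one another; the joint covariate
distribution of a real cohort (e.g. the height-BMI correlation) is not
modelled, since only the marginal adjustment code path depends on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CqMatrix

__all__ = [
    "ParameterError",
    "MirnaSpec",
    "MrnaBlockParams",
    "SimulationParams",
    "MrnaResult",
    "default_mirna_specs",
    "simulate_participants",
    "simulate_cq_matrix",
    "simulate_grip",
    "simulate_mrna",
    "simulate_cell_counts",
    "make_geneset_fixture",
    "make_prediction_fixture",
    "make_signature_fixture",
]


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class MirnaSpec:
    """One simulated miRNA assay.

    ``target_detection_fraction`` fixes the expected share of assayed
    participants whose latent Cq falls at or below the detection limit; the
    latent Gaussian is location-shifted to achieve it.  ``beta_continuous``
    (kg per Cq unit) and ``beta_binary`` (kg, undetected vs detected) are the
    planted grip effects; both zero makes a null miRNA.  ``assay_fraction``
    < 1 marks a random complement of participants as never assayed,
    reproducing panels measured in only part of a cohort.
    """

    name: str
    target_detection_fraction: float = 0.95
    latent_cq_mean: float = 24.0
    latent_cq_sd: float = 2.0
    beta_continuous: float = 0.0
    beta_binary: float = 0.0
    assay_fraction: float = 1.0

    def __post_init__(self) -> None:
        _check_fraction("target_detection_fraction", self.target_detection_fraction)
        _check_fraction("assay_fraction", self.assay_fraction)
        if self.latent_cq_sd < 0:
            raise ParameterError("latent_cq_sd must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.beta_continuous == 0.0 and self.beta_binary == 0.0


@dataclass
class MrnaBlockParams:
    """Coexpressed mRNA block layout: per selected miRNA, ``genes_per_mirna``
    genes correlated with the miRNA's detected Cq at strength ``correlation``,
    plus ``n_null_genes`` independent genes shared across the matrix."""

    genes_per_mirna: int = 20
    correlation: float = 0.5
    n_null_genes: int = 500
    block_mirnas: list[str] | None = None  # None: every non-null miRNA

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise ParameterError("correlation must lie strictly inside (-1, 1)")
        if self.genes_per_mirna < 0 or self.n_null_genes < 0:
            raise ParameterError("gene counts must be >= 0")


@dataclass
class SimulationParams:
    """Full description of one synthetic cohort.

    Scalar-or-pair fields accept a single value (shared across sexes) or a
    ``(men, women)`` pair; grip variance differs markedly by sex in real
    cohorts, so the defaults use pairs for the age slope and residual SD.
    """

    n_participants: int = 5668
    n_families: int = 1900
    family_sd: float = 3.0  # kg, random-intercept SD shared by all outcomes
    residual_sd: float | tuple[float, float] = (7.95, 4.15)  # kg
    prop_women: float = 0.54
    age_mean: float = 55.7
    age_sd: float = 13.2
    age_range: tuple[float, float] = (24.0, 90.0)
    grip_intercept_by_sex: tuple[float, float] = (44.7, 26.5)  # kg (men, women)
    grip_age_slope: float | tuple[float, float] = (-0.35, -0.18)  # kg / year
    grip_age_quad: float = -0.003  # kg / year^2
    height_effect: float = 0.4  # kg per inch above the sex mean
    bmi_effect: float = 0.10  # kg per kg m^-2 above the sex mean
    height_by_sex: tuple[tuple[float, float], tuple[float, float]] = (
        (69.3, 2.67),
        (63.9, 2.5),
    )  # (mean, sd) inches, (men, women)
    bmi_by_sex: tuple[tuple[float, float], tuple[float, float]] = (
        (29.0, 4.9),
        (27.3, 6.1),
    )  # (mean, sd) kg m^-2
    mirna_specs: list[MirnaSpec] = field(default_factory=lambda: default_mirna_specs())
    mrna_specs: MrnaBlockParams = field(default_factory=MrnaBlockParams)
    detection_threshold: float = 27.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_families > self.n_participants:
            raise ParameterError("n_families must not exceed n_participants")
        if self.n_families < 1:
            raise ParameterError("need at least one family")
        _check_fraction("prop_women", self.prop_women)
        for nm in ("family_sd", "age_sd"):
            if getattr(self, nm) < 0:
                raise ParameterError(f"{nm} must be >= 0")
        for v in np.atleast_1d(np.asarray(self.residual_sd, dtype=float)):
            if v < 0:
                raise ParameterError("residual_sd must be >= 0")

    def by_sex(self, value: float | tuple[float, float]) -> tuple[float, float]:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        return (float(arr[0]), float(arr[-1]))


def default_mirna_specs(n_mirnas: int = 299) -> list[MirnaSpec]:
    """Deterministic panel emulating a whole-blood qPCR miRNA study.

    Detection fractions follow a right-skewed grid from ~2% to 100% (most
    assays detect in most participants, a tail detects rarely).  Roughly 30%
    of miRNAs carry a planted effect: mostly negative continuous betas in
    the -0.10 to -0.30 kg/Cq range (higher expression, stronger grip), a
    sparse minority with positive betas, and binary effects of about -1 kg
    for the low-detection assays.  Every 25th assay covers only ~26% of the
    cohort, mimicking panels rolled out to a sub-sample.
    """
    grid = np.linspace(0.004, 0.996, n_mirnas)
    fractions = stats.beta.ppf(grid, 0.45, 0.16)  # mass near 1, tail near 0
    specs: list[MirnaSpec] = []
    for i in range(n_mirnas):
        frac = float(np.clip(fractions[i], 0.01, 1.0))
        if frac > 0.985:
            frac = 1.0
        beta_c = 0.0
        beta_b = 0.0
        if i % 10 < 3:  # ~30% non-null
            if i % 40 == 20:
                beta_c = 0.15  # occasional negative association with grip
            else:
                beta_c = -(0.10 + 0.20 * ((i * 37) % 100) / 100.0)
            if frac < 0.5:
                beta_b = -1.0
        specs.append(
            MirnaSpec(
                name=f"miR-sim-{i:04d}",
                target_detection_fraction=frac,
                latent_cq_mean=24.0,
                latent_cq_sd=2.0,
                beta_continuous=beta_c,
                beta_binary=beta_b,
                assay_fraction=0.26 if (i % 25 == 13) else 1.0,
            )
        )
    return specs


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage
    return np.random.default_rng([params.seed & 0x7FFFFFFF, stream])


def simulate_participants(params: SimulationParams) -> pd.DataFrame:
    """Draw the participant table: identifiers, covariates and family effects.

    The grip column is absent; :func:`simulate_grip` adds it once the Cq
    matrix exists.  ``sim_family_effect`` is the per-family random intercept
    (generator truth, not part of the cohort file dialect).
    """
    rng = _rng(params, 1)
    n = params.n_participants
    family_idx = rng.integers(0, params.n_families, size=n)
    family_effects = rng.normal(0.0, params.family_sd, size=params.n_families)
    women = rng.random(n) < params.prop_women

    if params.age_sd == 0:
        age = np.full(n, params.age_mean)
    else:
        lo, hi = params.age_range
        a = (lo - params.age_mean) / params.age_sd
        b = (hi - params.age_mean) / params.age_sd
        age = stats.truncnorm.rvs(
            a, b, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
        )

    (h_mean_m, h_sd_m), (h_mean_w, h_sd_w) = params.height_by_sex
    (b_mean_m, b_sd_m), (b_mean_w, b_sd_w) = params.bmi_by_sex
    height = np.where(
        women,
        rng.normal(h_mean_w, h_sd_w, n),
        rng.normal(h_mean_m, h_sd_m, n),
    )
    bmi = np.where(
        women,
        rng.normal(b_mean_w, b_sd_w, n),
        rng.normal(b_mean_m, b_sd_m, n),
    )

    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "family_id": [f"F{j:05d}" for j in family_idx],
            "sex": np.where(women, "F", "M"),
            "age": age,
            "height_in": height,
            "bmi": bmi,
            # technical covariates: independent Gaussians that exercise the
            # adjustment code path, not a model of assay physics
            "rna_conc": rng.normal(100.0, 25.0, n),
            "ratio_260_280": rng.normal(2.0, 0.12, n),
            "rna_quality": rng.normal(7.0, 1.5, n),
            "sim_family_effect": family_effects[family_idx],
        }
    )
    return cohort


def _latent_mean(spec: MirnaSpec, threshold: float) -> float:
    f = spec.target_detection_fraction
    if spec.latent_cq_sd == 0:
        if f not in (0.0, 1.0):
            raise ParameterError(
                f"{spec.name}: detection fraction {f} unreachable with latent_cq_sd=0"
            )
        return threshold if f == 1.0 else threshold + 1.0
    if f == 1.0:
        # fully detected: push the latent mean 8 SD below the limit so the
        # censoring probability is numerically zero
        return threshold - 8.0 * spec.latent_cq_sd
    if f == 0.0:
        return threshold + 8.0 * spec.latent_cq_sd
    # P(latent <= threshold) = f  =>  mean = threshold - sd * Phi^-1(f)
    return threshold - spec.latent_cq_sd * float(stats.norm.ppf(f))


def simulate_cq_matrix(cohort: pd.DataFrame, params: SimulationParams) -> CqMatrix:
    """Draw latent Cq per miRNA, censor at the detection limit, mask assays.

    Latent values above the threshold are recorded as undetected (+inf);
    a random ``1 - assay_fraction`` share of participants is marked not
    assayed (NaN), which is a distinct state excluded from both models.
    """
    rng = _rng(params, 2)
    n = len(cohort)
    thr = params.detection_threshold
    cols = {}
    for spec in params.mirna_specs:
        mu = _latent_mean(spec, thr)
        latent = rng.normal(mu, spec.latent_cq_sd, n)
        values = np.where(latent <= thr, latent, np.inf)
        if spec.assay_fraction < 1.0:
            not_assayed = rng.random(n) >= spec.assay_fraction
            values = np.where(not_assayed, np.nan, values)
        cols[spec.name] = values
    frame = pd.DataFrame(cols, index=pd.Index(cohort["participant_id"], name="participant_id"))
    return CqMatrix(frame, threshold=thr)


def simulate_grip(
    cohort: pd.DataFrame, cq: CqMatrix, params: SimulationParams
) -> pd.DataFrame:
    """Add the grip-strength column (kg) to a copy of the cohort table.

    grip = sex intercept + age trend + height/BMI terms + planted miRNA
    effects + family intercept + residual, floored at 0 kg.  The intercept
    equals the expected sex-stratified mean: the age terms are centred at
    ``age_mean`` and corrected for E[(age-mean)^2], and height/BMI are
    centred at their sex-specific means.  Continuous effects apply to Cq
    centred within the detected subset; binary effects to the undetected
    indicator; not-assayed entries contribute nothing.
    """
    if not cq.values.index.equals(pd.Index(cohort["participant_id"], name="participant_id")):
        raise ValueError("Cq matrix rows are not aligned to the cohort table")
    rng = _rng(params, 3)
    n = len(cohort)
    women = (cohort["sex"] == "F").to_numpy()
    icpt_m, icpt_w = params.grip_intercept_by_sex
    slope_m, slope_w = params.by_sex(params.grip_age_slope)
    res_m, res_w = params.by_sex(params.residual_sd)

    c_age = cohort["age"].to_numpy() - params.age_mean
    age_var = float(np.var(c_age)) if n > 1 else 0.0
    quad = params.grip_age_quad
    trend = (
        np.where(women, slope_w, slope_m) * c_age
        + quad * (c_age**2 - age_var)  # centred so the quadratic leaves means alone
    )

    (h_mean_m, _), (h_mean_w, _) = params.height_by_sex
    (b_mean_m, _), (b_mean_w, _) = params.bmi_by_sex
    c_height = cohort["height_in"].to_numpy() - np.where(women, h_mean_w, h_mean_m)
    c_bmi = cohort["bmi"].to_numpy() - np.where(women, b_mean_w, b_mean_m)

    grip = (
        np.where(women, icpt_w, icpt_m)
        + trend
        + params.height_effect * c_height
        + params.bmi_effect * c_bmi
        + cohort["sim_family_effect"].to_numpy()
        + np.where(women, res_w, res_m) * rng.standard_normal(n)
    )

    vals = cq.values.to_numpy()
    detected = np.isfinite(vals) & (vals <= cq.threshold)
    undetected = np.isposinf(vals) | (np.isfinite(vals) & (vals > cq.threshold))
    for j, spec in enumerate(params.mirna_specs):
        if spec.is_null:
            continue
        col = vals[:, j]
        det = detected[:, j]
        if spec.beta_continuous != 0.0 and det.any():
            centred = np.where(det, col - col[det].mean(), 0.0)
            grip = grip + spec.beta_continuous * centred
        if spec.beta_binary != 0.0:
            # centred indicator: the detected/undetected contrast is
            # beta_binary, but the population mean is left untouched
            ind = undetected[:, j].astype(float)
            grip = grip + spec.beta_binary * (ind - ind.mean())

    out = cohort.copy()
    out["grip_kg"] = np.maximum(grip, 0.0)
    return out


@dataclass
class MrnaResult:
    """Expression matrix plus generator truth for downstream fixtures."""

    expression: pd.DataFrame
    universe: list[str]
    block_genes: dict[str, list[str]]  # miRNA -> its correlated genes


def simulate_mrna(cq: CqMatrix, params: SimulationParams) -> MrnaResult:
    """Simulate mRNA expression with miRNA-correlated blocks plus null genes.

    Within each block, gene = r * z + sqrt(1-r^2) * noise where z is the
    miRNA's detected Cq standardised within the detected subset (zero
    elsewhere), so the gene-miRNA correlation among detected samples equals
    the declared block correlation.
    """
    rng = _rng(params, 4)
    block = params.mrna_specs
    idx = cq.values.index
    n = len(idx)
    names = block.block_mirnas
    if names is None:
        names = [s.name for s in params.mirna_specs if not s.is_null and s.name in cq.values.columns]
    cols: dict[str, np.ndarray] = {}
    block_genes: dict[str, list[str]] = {}
    r = block.correlation
    for mirna in names:
        col = cq.values[mirna].to_numpy()
        det = np.isfinite(col) & (col <= cq.threshold)
        z = np.zeros(n)
        if det.sum() >= 2 and np.std(col[det]) > 0:
            z[det] = (col[det] - col[det].mean()) / col[det].std()
        genes = [f"GENE_{mirna}_{j:03d}" for j in range(block.genes_per_mirna)]
        block_genes[mirna] = genes
        for g in genes:
            cols[g] = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    for k in range(block.n_null_genes):
        cols[f"GENE_NULL_{k:04d}"] = rng.standard_normal(n)
    expr = pd.DataFrame(cols, index=idx)
    return MrnaResult(expression=expr, universe=list(expr.columns), block_genes=block_genes)


def simulate_cell_counts(
    cohort: pd.DataFrame,
    expression: pd.DataFrame,
    measured_fraction: float = 0.6,
    noise_sd: float = 0.5,
    seed: int = 0,
    variables: tuple[str, ...] = ("rbc", "wbc", "platelets", "pct_neutrophil"),
) -> pd.DataFrame:
    """Blood cell counts as linear functions of a few expression components.

    Counts are measured (non-missing) only for a random ``measured_fraction``
    of participants, mirroring panels assayed in one sub-cohort; the rest are
    left missing for the imputation step to fill.
    """
    _check_fraction("measured_fraction", measured_fraction)
    rng = np.random.default_rng(seed)
    X = expression.to_numpy()
    n, p = X.shape
    counts = pd.DataFrame(index=expression.index)
    for v, name in enumerate(variables):
        w = np.zeros(p)
        picks = rng.choice(p, size=min(3, p), replace=False)
        w[picks] = rng.normal(1.0, 0.3, size=len(picks))
        counts[name] = 5.0 + X @ w + noise_sd * rng.standard_normal(n)
    measured = rng.random(n) < measured_fraction
    counts[~measured] = np.nan
    counts.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    return counts


def make_geneset_fixture(
    block_genes: list[str],
    n_sets: int,
    set_size: int,
    universe: list[str],
    seed: int = 0,
    planted_fraction: float = 0.8,
    path: str | None = None,
) -> dict[str, list[str]]:
    """Gene-set collection with one set deliberately enriched for the block.

    The first set (``planted_set``) takes ``planted_fraction`` of its members
    from ``block_genes``; the remaining sets are uniform draws from the
    universe.  Written as GMT when ``path`` is given.
    """
    universe = list(dict.fromkeys(universe))
    missing = set(block_genes) - set(universe)
    if missing:
        raise ParameterError(f"block genes absent from universe: {sorted(missing)[:5]}")
    if set_size > len(universe):
        raise ParameterError("set_size exceeds the universe size")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    if n_sets >= 1:
        k_block = min(len(block_genes), int(math.ceil(planted_fraction * set_size)))
        planted = list(rng.choice(block_genes, size=k_block, replace=False))
        others = [g for g in universe if g not in set(planted)]
        planted += list(rng.choice(others, size=set_size - k_block, replace=False))
        sets["planted_set"] = planted
    for s in range(1, n_sets):
        sets[f"random_set_{s:03d}"] = list(
            rng.choice(universe, size=set_size, replace=False)
        )
    if path is not None:
        from .io import write_gmt

        write_gmt(sets, path)
    return sets


def make_prediction_fixture(
    block_genes: dict[str, list[str]],
    universe: list[str],
    hit_fraction: float = 0.5,
    n_decoys: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Target-prediction pairs: part of each block plus random decoy pairs."""
    _check_fraction("hit_fraction", hit_fraction)
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    for mirna, genes in block_genes.items():
        k = int(round(hit_fraction * len(genes)))
        for g in rng.choice(genes, size=k, replace=False):
            rows.append((mirna, str(g)))
    mirnas = list(block_genes)
    if mirnas:
        for _ in range(n_decoys):
            rows.append((str(rng.choice(mirnas)), str(rng.choice(universe))))
    return pd.DataFrame(sorted(set(rows)), columns=["mirna", "gene"])


def make_signature_fixture(
    block_genes: dict[str, list[str]],
    universe: list[str],
    n_genes: int = 150,
    block_share: float = 0.2,
    seed: int = 0,
) -> list[str]:
    """A gene signature overlapping the simulated blocks, e.g. a healthy-aging
    muscle signature: ``block_share`` of its members come from block genes."""
    rng = np.random.default_rng(seed)
    pool = sorted({g for genes in block_genes.values() for g in genes})
    k = min(len(pool), int(round(block_share * n_genes)))
    sig = list(rng.choice(pool, size=k, replace=False)) if k else []
    rest = [g for g in universe if g not in set(sig)]
    sig += list(rng.choice(rest, size=min(n_genes - k, len(rest)), replace=False))
    return sorted(sig)
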