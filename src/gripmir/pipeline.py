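"""End-to-end orchestration: simulate -> associate -> permute -> coexpress ->
enrich -> report, driven by one YAML config, with a checksum manifest.

The run directory is the unit of reproducibility: identical configs (and
hence identical seeds) produce byte-identical stage outputs and manifests.
The manifest deliberately records no timestamps or host details.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from . import simulate as sim
from .association import AssociationOptions, associate_all, results_to_frame
from .coexpression import (
    coexpress_pairs,
    enrichment_to_frame,
    hypergeom_enrich,
    pairs_to_frame,
    select_top_mirnas,
    signature_overlap,
    targetscan_overlap,
)
from .io import (
    read_gmt,
    write_cohort,
    write_cq_matrix,
    write_expression,
    write_predictions,
)
from .multiple_testing import PermutationPlan, permutation_calibration
from .report import render_report

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_config"]

logger = logging.getLogger("gripmir")

STAGES = ("simulate", "associate", "permute", "coexpress", "enrich", "report")

DEFAULT_COVARIATES = [
    "sex", "age", "height_in", "bmi", "rna_conc", "ratio_260_280", "rna_quality",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "runs/demo"
    seed: int = 7
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    detection_threshold: float = 27.0
    eligibility_fraction: float = 0.05
    lower_cutoff: float = 0.10
    upper_cutoff: float = 0.90
    fdr_thresholds: tuple[float, ...] = (0.10, 0.05, 0.01, 0.001)
    k_top: int = 15
    n_permutation_replicates: int = 100
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.eligibility_fraction <= self.lower_cutoff:
            raise ValueError("need 0 < eligibility_fraction <= lower_cutoff")
        if not self.lower_cutoff < self.upper_cutoff <= 1.0:
            raise ValueError("need lower_cutoff < upper_cutoff <= 1")
        if list(self.fdr_thresholds) != sorted(self.fdr_thresholds, reverse=True):
            raise ValueError("fdr_thresholds must be strictly descending")
        if self.k_top < 0 or self.n_permutation_replicates < 1:
            raise ValueError("k_top must be >= 0 and n_permutation_replicates >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fdr_thresholds" in raw:
            raw["fdr_thresholds"] = tuple(raw["fdr_thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        # out_dir is omitted: it is implied by where the file sits, and
        # keeping it out makes runs into different directories but with the
        # same settings byte-identical (manifest checksum equality).
        data = {
            f.name: getattr(self, f.name) for f in dc_fields(self) if f.name != "out_dir"
        }
        data["fdr_thresholds"] = list(self.fdr_thresholds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def build_simulation_params(self) -> sim.SimulationParams:
        """Materialise SimulationParams from the ``simulation`` sub-config.

        Recognised convenience keys: ``n_mirnas`` (size of the default miRNA
        panel) and ``mrna`` (MrnaBlockParams fields); all other keys map
        directly onto SimulationParams fields.
        """
        cfg = dict(self.simulation)
        n_mirnas = cfg.pop("n_mirnas", None)
        mrna_cfg = cfg.pop("mrna", None)
        kwargs: dict = dict(cfg)
        if n_mirnas is not None:
            kwargs["mirna_specs"] = sim.default_mirna_specs(int(n_mirnas))
        if mrna_cfg is not None:
            kwargs["mrna_specs"] = sim.MrnaBlockParams(**mrna_cfg)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("detection_threshold", self.detection_threshold)
        valid = {f.name for f in dc_fields(sim.SimulationParams)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return sim.SimulationParams(**kwargs)


def default_config(out_dir: str = "runs/demo", seed: int = 7) -> PipelineConfig:
    """Desk-scale demo configuration: a 2000-participant cohort with a
    40-miRNA panel and small coexpression blocks.  Large enough for the
    stronger planted effects to clear FDR < 0.05, small enough that the
    whole pipeline (including 100 permutation replicates) runs in about
    two minutes."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        simulation={
            "n_participants": 2000,
            "n_families": 660,
            "n_mirnas": 40,
            "mrna": {"genes_per_mirna": 8, "correlation": 0.5, "n_null_genes": 120},
        },
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    manifest is written only after all stages succeed.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    artifacts: dict[str, list[str]] = {}
    current = "simulate"
    try:
        params = config.build_simulation_params()
        cohort = sim.simulate_participants(params)
        cq = sim.simulate_cq_matrix(cohort, params)
        cohort = sim.simulate_grip(cohort, cq, params)
        mrna = sim.simulate_mrna(cq, params)
        public_cols = [c for c in cohort.columns if not c.startswith("sim_")]
        write_cohort(cohort[public_cols], run_dir / "cohort.tsv")
        write_cq_matrix(cq, run_dir / "cq_matrix.tsv")
        write_expression(mrna.expression, run_dir / "mrna_matrix.tsv")
        sim.make_geneset_fixture(
            block_genes=sorted({g for gs in mrna.block_genes.values() for g in gs}),
            n_sets=20,
            set_size=min(50, max(5, len(mrna.universe) // 10)),
            universe=mrna.universe,
            seed=params.seed & 0x7FFFFFFF,
            path=str(run_dir / "gene_sets.gmt"),
        )
        predictions = sim.make_prediction_fixture(
            mrna.block_genes, mrna.universe, seed=params.seed & 0x7FFFFFFF
        )
        write_predictions(predictions, run_dir / "target_predictions.tsv")
        signature = sim.make_signature_fixture(
            mrna.block_genes, mrna.universe, seed=params.seed & 0x7FFFFFFF
        )
        (run_dir / "signature_genes.txt").write_text("\n".join(signature) + "\n")
        artifacts["simulate"] = [
            "cohort.tsv", "cq_matrix.tsv", "mrna_matrix.tsv",
            "gene_sets.gmt", "target_predictions.tsv", "signature_genes.txt",
        ]

        current = "associate"
        opts = AssociationOptions(
            lower_cutoff=config.lower_cutoff,
            upper_cutoff=config.upper_cutoff,
            eligibility_fraction=config.eligibility_fraction,
        )
        results = associate_all(cohort, cq, config.covariates, opts)
        results_to_frame(results).to_csv(run_dir / "association.tsv", sep="\t", index=False)
        artifacts["associate"] = ["association.tsv"]

        current = "permute"
        plan = PermutationPlan(
            n_replicates=config.n_permutation_replicates, seed=config.seed & 0x7FFFFFFF
        )
        calib = permutation_calibration(cohort, cq, config.covariates, plan, opts)
        (run_dir / "calibration.json").write_text(
            json.dumps(calib.to_dict(), indent=2, sort_keys=True)
        )
        artifacts["permute"] = ["calibration.json"]

        current = "coexpress"
        top = select_top_mirnas(results, config.k_top)
        pairs = coexpress_pairs(
            cq, mrna.expression, top, config.covariates, cohort
        )
        n_predicted = targetscan_overlap(pairs, predictions)
        sig_pairs, n_sig_genes = signature_overlap(pairs, signature)
        pairs_frame = pairs_to_frame(pairs)
        pairs_frame.to_csv(run_dir / "coexpression_pairs.tsv", sep="\t", index=False)
        n_sig = int(pairs_frame["significant"].sum())
        coexp_summary = {
            "top_mirnas": top,
            "n_pairs_tested": len(pairs),
            "n_significant_pairs": n_sig,
            "n_unique_genes": int(pairs_frame.loc[pairs_frame["significant"], "gene"].nunique()),
            "n_predicted_significant": int(n_predicted),
            "n_signature_pairs": len(sig_pairs),
            "n_signature_genes": int(n_sig_genes),
        }
        (run_dir / "coexpression_summary.json").write_text(
            json.dumps(coexp_summary, indent=2, sort_keys=True)
        )
        artifacts["coexpress"] = ["coexpression_pairs.tsv", "coexpression_summary.json"]

        current = "enrich"
        selected = sorted(pairs_frame.loc[pairs_frame["significant"], "gene"].unique())
        gene_sets = read_gmt(run_dir / "gene_sets.gmt")
        enr = hypergeom_enrich(selected, gene_sets, mrna.universe)
        enrichment_to_frame(enr).to_csv(run_dir / "enrichment.tsv", sep="\t", index=False)
        artifacts["enrich"] = ["enrichment.tsv"]

        current = "report"
        (run_dir / "report.md").write_text(render_report(run_dir, k_top=config.k_top))
        artifacts["report"] = ["report.md"]
    except Exception as exc:
        raise PipelineError(current, exc) from exc

    manifest = {
        "seed": config.seed,
        "stages": [
            {
                "name": stage,
                "outputs": {
                    name: _sha256(run_dir / name) for name in artifacts[stage]
                },
            }
            for stage in STAGES
        ],
        "config": _sha256(run_dir / "config.yaml"),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", run_dir)
    return run_dir
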