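"""Reading and writing the package's tabular formats.

Conventions (fixed, documented here once):

* Cohort tables are tab-separated text with one header row.
* Cq and expression matrices are tab-separated with participants as rows
  (index column ``participant_id``) and features as columns.  In Cq matrices
  an undetected assay (signal never crossed threshold within the instrument's
  cycle budget) is written ``ND``; a cell left empty means the miRNA was not
  assayed in that participant at all.  In memory these map to ``+inf``
  (undetected: censored at high Cq, i.e. low expression) and ``NaN``
  (not assayed).
* Gene sets use GMT: one set per line, ``name <tab> description <tab> gene...``.
* Target-prediction tables are two-column TSV ``mirna <tab> gene``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "UNDETECTED",
    "read_cohort",
    "write_cohort",
    "read_cq_matrix",
    "write_cq_matrix",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_predictions",
    "write_predictions",
]

#: sentinel for a censored (undetected) qPCR reaction
UNDETECTED = np.inf

_ND = "ND"


@dataclass
class CqMatrix:
    """Participants x miRNAs Cq values with censoring metadata.

    ``values`` holds detected Cq as finite floats, ``+inf`` for undetected
    (censored at the detection limit) and ``NaN`` for not assayed.
    ``threshold`` is the instrument detection limit in cycles: a finite Cq
    strictly above it is also treated as undetected by the association code.
    """

    values: pd.DataFrame
    threshold: float = 27.0

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @property
    def mirnas(self) -> list[str]:
        return list(self.values.columns)

    def assayed_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def detected_mask(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            return self.values.le(self.threshold) & self.values.notna()

    def detection_summary(self) -> pd.DataFrame:
        """Per-miRNA assayed / detected counts and detected fraction."""
        assayed = self.assayed_mask().sum(axis=0)
        detected = self.detected_mask().sum(axis=0)
        return pd.DataFrame(
            {
                "n_assayed": assayed,
                "n_detected": detected,
                "detected_fraction": detected / assayed.replace(0, np.nan),
            }
        )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cq_matrix(cq: CqMatrix, path: str | Path) -> None:
    out = cq.values.copy().astype(object)
    out[np.isposinf(cq.values.to_numpy())] = _ND
    out.to_csv(path, sep="\t", index=True, index_label="participant_id", na_rep="")


def read_cq_matrix(path: str | Path, threshold: float = 27.0) -> CqMatrix:
    raw = pd.read_csv(
        path, sep="\t", index_col="participant_id", dtype=str, keep_default_na=False
    )
    vals = raw.replace({_ND: np.inf, "": np.nan}).astype(float)
    return CqMatrix(vals, threshold=threshold)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=True, index_label="participant_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="participant_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    if list(df.columns[:2]) != ["mirna", "gene"]:
        df.columns = ["mirna", "gene", *df.columns[2:]]
    return df[["mirna", "gene"]].dropna()


def write_predictions(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[["mirna", "gene"]].to_csv(path, sep="\t", index=False)
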