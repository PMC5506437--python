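import numpy as np
import pytest

from gripmir.simulate import (
    MirnaSpec,
    MrnaBlockParams,
    SimulationParams,
    simulate_cq_matrix,
    simulate_grip,
    simulate_participants,
)

COVARIATES = ["sex", "age", "height_in", "bmi", "rna_conc", "ratio_260_280", "rna_quality"]


@pytest.fixture(scope="session")
def covariates():
    return list(COVARIATES)


def small_params(seed=101, n=600, **kwargs):
    """A cheap cohort spanning all four branches (ineligible .. continuous)."""
    specs = kwargs.pop(
        "mirna_specs",
        [
            MirnaSpec("miR-inelig", 0.03),
            MirnaSpec("miR-low", 0.07),
            MirnaSpec("miR-mid", 0.50, beta_continuous=-0.3),
            MirnaSpec("miR-high", 0.95),
            MirnaSpec("miR-all", 1.0),
        ],
    )
    return SimulationParams(
        n_participants=n,
        n_families=max(2, n // 3),
        mirna_specs=specs,
        mrna_specs=kwargs.pop(
            "mrna_specs", MrnaBlockParams(genes_per_mirna=5, correlation=0.5, n_null_genes=20)
        ),
        seed=seed,
        **kwargs,
    )


def build_cohort(params):
    cohort = simulate_participants(params)
    cq = simulate_cq_matrix(cohort, params)
    cohort = simulate_grip(cohort, cq, params)
    return cohort, cq


@pytest.fixture(scope="session")
def small_cohort():
    params = small_params()
    cohort, cq = build_cohort(params)
    return params, cohort, cq


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
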