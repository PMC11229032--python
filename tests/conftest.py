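import numpy as np
import pytest

from cartarget import (
    CohortSpec,
    build_cohort,
    simulate_celllines,
    simulate_cohort,
)

PLANTED_GENES = ["G00001", "G00005", "G00009"]


@pytest.fixture(scope="session")
def small_sim():
    """200-gene cohort, 3 genes planted at 16-fold overexpression."""
    spec = CohortSpec(
        seed=20240701,
        n_genes=200,
        planted=[(g, "primary_tumor", 16.0) for g in PLANTED_GENES],
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return build_cohort(
        "COAD", small_sim.tcga, small_sim.gtex, small_sim.annotations,
        small_sim.cohort_map,
    )


@pytest.fixture(scope="session")
def null_sim():
    """200-gene cohort with no planted signals."""
    spec = CohortSpec(seed=777, n_genes=200)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def cellline_panel():
    """Three-tier bowel panel mirroring a high/medium/low validation set."""
    return simulate_celllines(
        n_genes=30,
        lineages={"Bowel": ["HI-LINE", "MID-LINE", "LO-LINE"], "Lung": 4},
        planted=[
            ("CEAC", "HI-LINE", 1270.0),
            ("CEAC", "MID-LINE", 635.0),
            ("CEAC", "LO-LINE", 241.0),
            ("CEAC", "Lung", 1.0),
        ],
        seed=42,
    )
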