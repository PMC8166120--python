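import numpy as np
import pytest

from voxelgrowth import GrowthTruth, SimulationConfig
from voxelgrowth.sem import LongTable, build_lgm_spec
from voxelgrowth.simulate import generate_cohort, generate_growth_panel

#: Truth with every path nonzero, used across recovery-style tests.
RICH_TRUTH = GrowthTruth(
    alpha_i=0.25, alpha_s=-0.02, gamma_im=0.02, gamma_sm=-0.05,
    gamma_ia=0.004, gamma_sa=-0.001, psi_ii=0.02, psi_ss=0.006,
    psi_is=0.002, theta=(0.02, 0.02, 0.02))


@pytest.fixture(scope="session")
def cond_spec():
    return build_lgm_spec(3, covariates=("mfq_fof", "age_c"))


@pytest.fixture(scope="session")
def cohort_records():
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_panel(cohort_records):
    """A 69-subject panel with realistic attrition."""
    return generate_growth_panel(cohort_records, RICH_TRUTH, seed=11)


@pytest.fixture(scope="session")
def fixture_panel():
    """The packaged 69-subject oracle fixture (69/34/28 pattern)."""
    import pandas as pd
    from pathlib import Path

    tab = pd.read_csv(Path(__file__).parent / "data" / "fixture_cohort69.tsv",
                      sep="\t")
    return LongTable.from_frame(tab, ["y1", "y2", "y3"],
                                ["mfq_fof", "age_c"])
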