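import numpy as np
import pandas as pd
import pytest

from carrierprs import (SimulationConfig, WeightTable, make_incidence_fixture,
                        simulate_retrospective_cohort)


@pytest.fixture(scope="session")
def breast_curve():
    return make_incidence_fixture(0.72, "breast")


@pytest.fixture(scope="session")
def ovarian_curve():
    return make_incidence_fixture(0.44, "ovarian")


@pytest.fixture(scope="session")
def small_weight_table():
    """Three-SNP table with known weights and frequencies for hand checks."""
    return WeightTable(pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3"],
        "chromosome": ["1", "2", "3"],
        "position": [100, 200, 300],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "weight": [0.1, -0.2, 0.05],
        "effect_allele_frequency": [0.5, 0.25, 0.1],
    }))


@pytest.fixture(scope="session")
def ascertained_cohort(breast_curve):
    """Mid-sized ascertained breast-cancer cohort under per-SD HR 1.29."""
    cfg = SimulationConfig(n_carriers=5000, beta0=np.log(1.29),
                           incidence=breast_curve, seed=42)
    cohort, truth = simulate_retrospective_cohort(cfg)
    return cohort, truth
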