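import numpy as np
import pytest

from spatialtme import (
    CohortSimConfig,
    CoreSimConfig,
    PhenotypeSimSpec,
    assign_phenotypes,
    default_rules,
    simulate_cohort,
    simulate_core,
)

#: True window of every simulated 1-mm core.
CIRCLE_WINDOW = ("circle", 1000.0)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def csr_core():
    """One simulated core with malignant and CSR T-cells at 100 cells/mm2."""
    cfg = CoreSimConfig(
        malignant_intensity=100.0,
        phenotype_specs=(PhenotypeSimSpec(name="CD3+", regime="csr",
                                          intensity=100.0),),
        seed=11,
    )
    return cfg, simulate_core(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject cohort with known groups and a group-4 hazard of ln 2."""
    cfg = CohortSimConfig(
        n_subjects=60,
        group_probabilities=(0.25, 0.30, 0.10, 0.35),
        log_hazard_by_group=(0.0, 0.0, 0.0, float(np.log(2.0))),
        seed=202,
    )
    cells, clinical = simulate_cohort(cfg)
    return cfg, cells, clinical


@pytest.fixture(scope="session")
def small_cohort_phenotyped(small_cohort, rules):
    cfg, cells, clinical = small_cohort
    return cfg, cells, clinical, assign_phenotypes(cells, rules)
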