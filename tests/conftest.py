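import numpy as np
import pandas as pd
import pytest

from ltfhpp import (
    FamilyPedigree,
    PersonRecord,
    SimulationConfig,
    build_incidence_surface,
    incidence_table_from_config,
)


@pytest.fixture
def trio_pedigree():
    """Index with both parents (no siblings)."""
    idx = PersonRecord("child", "fam1", "index", sex="male")
    father = PersonRecord("dad", "fam1", "father", sex="male")
    mother = PersonRecord("mum", "fam1", "mother", sex="female")
    return FamilyPedigree(index=idx, relatives=(father, mother))


@pytest.fixture
def quad_pedigree():
    idx = PersonRecord("child", "fam2", "index", sex="female")
    father = PersonRecord("dad", "fam2", "father", sex="male")
    mother = PersonRecord("mum", "fam2", "mother", sex="female")
    sib = PersonRecord("sib", "fam2", "sibling", sex="male")
    return FamilyPedigree(index=idx, relatives=(father, mother, sib))


@pytest.fixture(scope="session")
def logistic_surface():
    """Linear-interpolated surface matching the simulator's true incidence."""
    cfg = SimulationConfig(n_families=10, n_snps=10, n_causal=5)
    return build_incidence_surface(
        incidence_table_from_config(cfg), interpolation="linear"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across tests (read-only)."""
    from ltfhpp import simulate_cohort

    cfg = SimulationConfig(
        n_families=4000,
        n_snps=40,
        n_causal=40,
        prevalence=0.05,
        downsample=True,
        seed=11,
    )
    return simulate_cohort(cfg)
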