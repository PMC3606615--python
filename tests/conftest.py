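from __future__ import annotations

import numpy as np
import pytest

from hwesurvey import FamilyData, SimulationConfig
from hwesurvey.simulate import (
    assign_weights,
    generate_population,
    sample_psus,
)

#: one Mendelian-consistent trio per familial type, in type order
TYPE_EXEMPLARS = [
    (0, 0, 0),
    (0, 1, 0),
    (0, 1, 1),
    (0, 2, 1),
    (1, 1, 0),
    (1, 1, 1),
    (1, 1, 2),
    (1, 2, 1),
    (1, 2, 2),
    (2, 2, 2),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def ten_family_data() -> FamilyData:
    """One family per familial type, unit weights, 5 PSUs of 2 in one stratum."""
    n = 10
    return FamilyData(
        stratum=np.zeros(n, dtype=int),
        psu=np.arange(n) // 2,
        family_id=np.arange(n),
        genotypes=np.array(TYPE_EXEMPLARS),
        family_weight=np.ones(n),
    )


def make_survey_sample(
    seed: int,
    r: float = 0.0,
    p_A: float = 0.3,
    weight_scheme: str = "unit",
    clustered: bool = False,
    n_psu_sample: int = 60,
):
    """A full simulated survey sample (default: 60 PSUs x 40 families)."""
    from hwesurvey.simulate import cluster_population

    cfg = SimulationConfig(
        p_A=p_A, r=r, clustered=clustered,
        n_psu_sample=n_psu_sample, weight_scheme=weight_scheme,
    )
    gen = np.random.default_rng(np.random.SeedSequence(seed))
    pop = generate_population(cfg, gen)
    if clustered:
        pop = cluster_population(pop)
    data, design = sample_psus(pop, cfg, gen)
    return assign_weights(data, weight_scheme, gen), design


@pytest.fixture
def survey_sample():
    """Unit-weight 60-PSU null sample plus its design."""
    return make_survey_sample(seed=42)


def independent_families(
    n: int, seed: int, p_A: float = 0.3, r: float = 0.0
) -> FamilyData:
    """n independent trio families, each its own PSU, one stratum, unit weights."""
    cfg = SimulationConfig(
        p_A=p_A, r=r, n_psu_pop=n, families_per_psu=1, n_psu_sample=n
    )
    gen = np.random.default_rng(np.random.SeedSequence(seed))
    pop = generate_population(cfg, gen)
    return FamilyData(
        stratum=np.zeros(n, dtype=int),
        psu=np.arange(n),
        family_id=np.arange(n),
        genotypes=pop.genotypes,
        family_weight=np.ones(n),
    )
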