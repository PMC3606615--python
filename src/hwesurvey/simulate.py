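"""Finite-population trio simulators for the Monte-Carlo study and the
household-survey demonstration frame.

The study population holds ``n_psu_pop`` PSUs of ``families_per_psu`` trio
families each (defaults 2,500 x 40 = 100,000 families, 300,000 people).
Parental genotypes are independent draws from the fixation-index
distribution; children follow Mendelian transmission.  Two scenarios:

* independent — families keep their generation-order PSUs, so families
  within a PSU are independent;
* clustered — all families are stably sorted by their within-family count
  of genotype ``aa`` (0-3) and regrouped into consecutive blocks, producing
  strong intra-PSU correlation of the genetic data.

A sample takes a simple random sample of PSUs (default 60), keeps every
family in each sampled PSU, and assigns either unit weights or the
noninformative {1, 3, 5}-thirds scheme.

The demonstration frame emulates a national household survey with 307 trio
families on a synthetic stratified multistage design: within-family
screening weights {2, 1.33, 1} by age class, synthetic final weights, and
family weights formed by averaging members' (final / within-family)
weights.  Genotypes come from the two-step compound model: a per-family
allele frequency drawn from Beta((1-r) f_A / r, (1-r)(1-f_A) / r) — whose
variance r f_A (1-f_A) makes the within-family allele correlation equal
the fixation index r — then parental allele pairs Bin(2, p_A) and a
Mendelian child.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import FamilyData, SurveyDesign
from .genotypes import GenotypeModel, genotype_distribution

WEIGHT_SCHEMES = ("unit", "thirds_1_3_5")


@dataclass
class SimulationConfig:
    """Population, design and weighting parameters of one study scenario."""

    p_A: float = 0.3
    r: float = 0.0
    n_psu_pop: int = 2500
    families_per_psu: int = 40
    clustered: bool = False
    n_psu_sample: int = 60
    weight_scheme: str = "unit"

    def __post_init__(self) -> None:
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"weight_scheme must be one of {WEIGHT_SCHEMES}")
        if self.n_psu_sample > self.n_psu_pop:
            raise ValueError("cannot sample more PSUs than the population holds")
        if not 0.0 <= self.r < 1.0:
            raise ValueError("population fixation index must be in [0, 1)")

    @property
    def population_size(self) -> int:
        """Number of individuals: families x 3."""
        return self.n_psu_pop * self.families_per_psu * 3


@dataclass
class Population:
    """A generated finite population of trio families grouped in PSUs.

    Families are stored in PSU order: family ``i`` belongs to PSU
    ``i // families_per_psu``.
    """

    genotypes: np.ndarray  # (n_families, 3) int8
    families_per_psu: int
    family_index: np.ndarray = field(default=None)  # original generation order

    def __post_init__(self) -> None:
        if self.family_index is None:
            self.family_index = np.arange(len(self.genotypes))

    @property
    def n_families(self) -> int:
        return len(self.genotypes)

    @property
    def n_psus(self) -> int:
        return self.n_families // self.families_per_psu


def _draw_genotypes(n: int, p_A: float, r: float, rng: np.random.Generator) -> np.ndarray:
    probs = genotype_distribution(GenotypeModel(p_A=p_A, r=r))
    cum = np.cumsum(probs)
    return np.searchsorted(cum, rng.random(n), side="right").astype(np.int8)


def _mendelian_children(
    gf: np.ndarray, gm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One transmitted allele per parent; child code = copies of allele a."""
    n = len(gf)
    # transmitted-a indicator: AA -> 0, aa -> 1, Aa -> fair coin
    a_f = np.where(gf == 2, 1, np.where(gf == 0, 0, rng.integers(0, 2, n)))
    a_m = np.where(gm == 2, 1, np.where(gm == 0, 0, rng.integers(0, 2, n)))
    return (a_f + a_m).astype(np.int8)


def generate_population(cfg: SimulationConfig, rng: np.random.Generator) -> Population:
    """Generate the full finite population of trios under the fixation-index model."""
    n = cfg.n_psu_pop * cfg.families_per_psu
    gf = _draw_genotypes(n, cfg.p_A, cfg.r, rng)
    gm = _draw_genotypes(n, cfg.p_A, cfg.r, rng)
    gc = _mendelian_children(gf, gm, rng)
    return Population(
        genotypes=np.column_stack([gf, gm, gc]),
        families_per_psu=cfg.families_per_psu,
    )


def cluster_population(pop: Population) -> Population:
    """Regroup families into PSUs correlated in their genetic makeup.

    Families are stably sorted by the within-family count of genotype
    ``aa`` (ties keep generation order) and consecutive blocks of
    ``families_per_psu`` become the new PSUs.
    """
    aa_count = (pop.genotypes == 2).sum(axis=1)
    order = np.argsort(aa_count, kind="stable")
    return Population(
        genotypes=pop.genotypes[order],
        families_per_psu=pop.families_per_psu,
        family_index=pop.family_index[order],
    )


def sample_psus(
    pop: Population, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[FamilyData, SurveyDesign]:
    """SRS of PSUs without replacement; every family in a sampled PSU is kept.

    The resulting design has a single stratum with ``n_psu_sample`` PSUs and
    unit weights (reassign with :func:`assign_weights`).
    """
    psu_ids = rng.choice(pop.n_psus, size=cfg.n_psu_sample, replace=False)
    fpp = pop.families_per_psu
    rows = (psu_ids[:, None] * fpp + np.arange(fpp)).ravel()
    n = len(rows)
    data = FamilyData(
        stratum=np.zeros(n, dtype=np.int64),
        psu=np.repeat(psu_ids, fpp),
        family_id=pop.family_index[rows],
        genotypes=pop.genotypes[rows],
        family_weight=np.ones(n),
    )
    design = SurveyDesign(
        psu_index=np.repeat(np.arange(cfg.n_psu_sample), fpp),
        psu_stratum=np.zeros(cfg.n_psu_sample, dtype=np.int64),
        H=1,
        U=cfg.n_psu_sample,
    )
    return data, design


def assign_weights(
    data: FamilyData,
    scheme: str,
    rng: np.random.Generator,
    individual_level: bool = False,
) -> FamilyData:
    """Attach sampling weights under the configured noninformative scheme.

    ``unit`` gives every family weight 1.  ``thirds_1_3_5`` partitions the
    sample uniformly at random into exact thirds receiving weights 1, 3
    and 5.  By default the weight is placed at the family level (all three
    members share it); with ``individual_level=True`` weights are assigned
    per individual and the family weight is the member mean.
    """
    if scheme == "unit":
        n = data.n_families
        return data.with_weights(np.ones(n))
    if scheme != "thirds_1_3_5":
        raise ValueError(f"unknown weight scheme {scheme!r}")
    values = np.array([1.0, 3.0, 5.0])
    if individual_level:
        n = 3 * data.n_families
        if n % 3:
            raise ValueError("member count not divisible into thirds")
        mw = np.repeat(values, n // 3)[rng.permutation(n)].reshape(-1, 3)
        return data.with_weights(mw.mean(axis=1), mw)
    n = data.n_families
    if n % 3:
        raise ValueError("family count not divisible into thirds")
    fw = np.repeat(values, n // 3)[rng.permutation(n)]
    return data.with_weights(fw)


@dataclass
class HhanesFrameConfig:
    """Synthetic stratified household-survey frame for the demonstration.

    307 trio families (921 individuals) spread over ``n_strata`` strata of
    ``psus_per_stratum`` PSUs.  ``f_A`` is the target allele-A frequency and
    ``r`` the fixation coefficient of the compound Beta/binomial genotype
    generator.  Within-family screening weights by age class default to the
    survey's subsampling rates (children 50% -> 2, parents 75% -> 1.33).
    """

    n_families: int = 307
    f_A: float = 0.3
    r: float = 0.0
    n_strata: int = 10
    psus_per_stratum: int = 3
    child_within_weight: float = 2.0
    parent_within_weight: float = 1.33

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 1.0:
            raise ValueError("fixation coefficient must be in [0, 1)")

    @property
    def n_individuals(self) -> int:
        return 3 * self.n_families


def draw_family_allele_freqs(
    cfg: HhanesFrameConfig, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Per-family allele frequencies from the compound Beta step.

    ``p_A ~ Beta((1-r) f_A / r, (1-r)(1-f_A) / r)`` when r > 0 (mean f_A,
    variance r f_A (1-f_A)); degenerate at f_A when r = 0.
    """
    size = cfg.n_families if size is None else size
    if cfg.r == 0.0:
        return np.full(size, cfg.f_A)
    alpha = (1 - cfg.r) * cfg.f_A / cfg.r
    beta = (1 - cfg.r) * (1 - cfg.f_A) / cfg.r
    return rng.beta(alpha, beta, size=size)


def generate_hhanes_frame(
    cfg: HhanesFrameConfig, rng: np.random.Generator
) -> tuple[FamilyData, SurveyDesign]:
    """Generate the synthetic demonstration frame with genotypes and weights.

    Per family: draw ``p_A`` from the compound Beta step, each parent's
    genotype as Bin(2, p_A) copies of allele A, a Mendelian child.  Final
    weights are synthetic (lognormal around a stratum base level, larger in
    higher-index strata), noninformative of the genotypes; the family
    weight averages the members' (final / within-family) weights.
    """
    n = cfg.n_families
    p_fam = draw_family_allele_freqs(cfg, rng)
    n_A_f = rng.binomial(2, p_fam)
    n_A_m = rng.binomial(2, p_fam)
    gf = (2 - n_A_f).astype(np.int8)
    gm = (2 - n_A_m).astype(np.int8)
    gc = _mendelian_children(gf, gm, rng)

    n_psus = cfg.n_strata * cfg.psus_per_stratum
    psu = np.arange(n) % n_psus
    stratum = psu // cfg.psus_per_stratum

    within = np.column_stack(
        [
            np.full(n, cfg.parent_within_weight),
            np.full(n, cfg.parent_within_weight),
            np.full(n, cfg.child_within_weight),
        ]
    )
    stratum_base = 1.0 + 0.5 * stratum  # oversampling gradient across strata
    base = rng.lognormal(mean=0.0, sigma=0.3, size=(n, 3)) * stratum_base[:, None]
    final = within * base
    family_weight = (final / within).mean(axis=1)

    data = FamilyData(
        stratum=stratum,
        psu=psu,
        family_id=np.arange(n),
        genotypes=np.column_stack([gf, gm, gc]),
        family_weight=family_weight,
        member_weights=final,
    )
    return data, SurveyDesign.from_family_data(data)
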