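"""Monte-Carlo driver: empirical size and power of the five HWE tests
under configured survey-sampling scenarios.

Each replicate regenerates the finite population, optionally clusters it,
draws a fresh PSU sample and weights, and runs all five tests; the
rejection rate of each test is the proportion of replicates with p-value
below ``alpha``.  Per-replicate random streams are spawned from the master
seed with a counter scheme, so every scenario is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ccs import ccs_test_suite
from .families import FamilyData, SurveyDesign
from .qs import qs_test
from .results import TestResult
from .simulate import (
    HhanesFrameConfig,
    SimulationConfig,
    assign_weights,
    cluster_population,
    generate_hhanes_frame,
    generate_population,
    sample_psus,
)

#: the five tests in reporting order
TEST_NAMES = ("chisq_naive", "chisq_rs1", "chisq_rs2", "chisq_rs2_F", "qs")

CCS_TEST_NAMES = TEST_NAMES[:4]


def run_all_tests(
    data: FamilyData,
    design: SurveyDesign | None = None,
    arrangement: str = "pairwise",
) -> dict[str, TestResult]:
    """All five statistics (four chi-square family + quasi-score) on one sample."""
    if design is None:
        design = SurveyDesign.from_family_data(data)
    out = ccs_test_suite(data, design)
    out["qs"] = qs_test(data, design, arrangement)
    return out


@dataclass
class RejectionTable:
    """Empirical rejection rates of the five tests for one scenario."""

    config: SimulationConfig
    alpha: float
    n_reps: int
    rates: dict[str, float]
    n_failed: int = 0

    def mc_se(self, test: str) -> float:
        p = self.rates[test]
        return float(np.sqrt(p * (1 - p) / self.n_reps))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test": list(self.rates),
                "rejection_rate": list(self.rates.values()),
                "mc_se": [self.mc_se(t) for t in self.rates],
                "n_reps": self.n_reps,
                "alpha": self.alpha,
            }
        )


def replicate_pvalues(
    cfg: SimulationConfig, rng: np.random.Generator, arrangement: str = "pairwise"
) -> dict[str, float]:
    """One Monte-Carlo replicate: generate, sample, weight, test."""
    pop = generate_population(cfg, rng)
    if cfg.clustered:
        pop = cluster_population(pop)
    data, design = sample_psus(pop, cfg, rng)
    data = assign_weights(data, cfg.weight_scheme, rng)
    results = run_all_tests(data, design, arrangement)
    return {name: results[name].p_value for name in TEST_NAMES}


def collect_pvalues(
    cfg: SimulationConfig,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
    arrangement: str = "pairwise",
) -> pd.DataFrame:
    """P-values of the five tests over ``n_reps`` replicates (rows).

    Replicates whose tests fail on a degenerate sample yield NaN rows.
    Per-replicate random streams are spawned from ``seed``, so replicate
    ``k`` is reproducible in isolation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rows = []
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        try:
            rows.append(replicate_pvalues(cfg, rng, arrangement))
        except (ValueError, RuntimeError):
            rows.append({name: np.nan for name in TEST_NAMES})
    return pd.DataFrame(rows, columns=list(TEST_NAMES))


def run_scenario(
    cfg: SimulationConfig,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    arrangement: str = "pairwise",
    max_failure_fraction: float = 0.01,
) -> RejectionTable:
    """Rejection rate of each test at level ``alpha`` over ``n_reps`` replicates.

    Replicates whose tests fail (degenerate samples) are excluded and
    counted; the run aborts if more than ``max_failure_fraction`` of
    replicates fail.
    """
    pvals = collect_pvalues(cfg, n_reps, seed, arrangement)
    n_failed = int(pvals.isna().any(axis=1).sum())
    if n_failed > max_failure_fraction * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} replicates failed; scenario is degenerate"
        )
    ok = pvals.dropna()
    rates = {name: float((ok[name] < alpha).mean()) for name in TEST_NAMES}
    return RejectionTable(
        config=cfg, alpha=alpha, n_reps=len(ok), rates=rates, n_failed=n_failed
    )


@dataclass
class StudyTable:
    """Rejection rates of several scenarios arranged tests x scenarios."""

    tables: list[RejectionTable] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for t in self.tables:
            label = (
                f"r={t.config.r:g}, w="
                + ("1" if t.config.weight_scheme == "unit" else "{1,3,5}")
            )
            cols[label] = [t.rates[name] for name in TEST_NAMES]
        return pd.DataFrame(cols, index=list(TEST_NAMES))

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="test")


def run_table(
    scenarios: list[SimulationConfig],
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    arrangement: str = "pairwise",
) -> StudyTable:
    """Run a list of scenarios (columns) and collect the five-test table.

    Each scenario receives an independent child stream of the master seed,
    so single columns can be reproduced in isolation with
    ``SeedSequence(seed).spawn(len(scenarios))[k]``.
    """
    streams = np.random.SeedSequence(seed).spawn(len(scenarios))
    return StudyTable(
        tables=[
            run_scenario(cfg, n_reps, alpha, stream, arrangement)
            for cfg, stream in zip(scenarios, streams)
        ]
    )


def run_hhanes_example(
    frame_cfg: HhanesFrameConfig,
    r_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    seed: int | np.random.SeedSequence = 0,
    arrangement: str = "pairwise",
) -> pd.DataFrame:
    """P-values of the four design-based tests on the demonstration frame.

    For each fixation coefficient in ``r_grid``, genotypes are regenerated
    on the synthetic 307-family frame and the first-order, second-order,
    F-version and quasi-score tests are run; the uncorrected chi-square is
    omitted, as it ignores the design.  Columns are r values, rows tests.
    """
    import dataclasses

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = ss.spawn(len(r_grid))
    names = ("chisq_rs1", "chisq_rs2", "chisq_rs2_F", "qs")
    cols = {}
    for r, stream in zip(r_grid, streams):
        cfg = dataclasses.replace(frame_cfg, r=r)
        data, design = generate_hhanes_frame(cfg, np.random.default_rng(stream))
        results = run_all_tests(data, design, arrangement)
        cols[f"r={r:g}"] = [results[n].p_value for n in names]
    return pd.DataFrame(cols, index=list(names))
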