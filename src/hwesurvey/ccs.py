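"""Weighted Pearson chi-square over the ten familial types and its
Rao-Scott corrections for complex survey designs.

The uncorrected statistic treats the weighted familial-type counts ``J_w``
as if they were multinomial:

    chi2_AW = theta^T M theta,   theta = J_w - T_w * pi_hat,
    M = [T_w diag(pi_hat)]^{-1}

with ``pi_hat`` the HWE type probabilities evaluated at the weighted allele
frequency.  Under clustered, weighted sampling this statistic is not
chi-square distributed; the Rao-Scott corrections rescale it by the
eigenvalues (generalized design effects) of ``Sigma_hat M``, where
``Sigma_hat`` is a Taylor-linearization estimate of the design-based
covariance of ``theta``:

* first order:  chi2 / lambda_bar, referred to chi-square(8);
* second order: additionally divided by (1 + b^2), with b^2 the squared CV
  of the eigenvalues, referred to chi-square with 8/(1+b^2) df;
* F version: the second-order statistic divided by its df, referred to
  F(8/(1+b^2), U - H).

Eight degrees of freedom: ten cells minus one (the counts sum to T_w) minus
one (the allele frequency is estimated from the same counts); the two
annihilated directions are ``1`` and the parental-allele-count vector ``c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .families import FamilyData, SurveyDesign
from .genotypes import (
    PARENTAL_ALLELE_COUNT,
    trio_type_prob_derivative,
    trio_type_probabilities,
)
from .results import TestResult

N_TYPES = 10
DF_FULL = 8  # 10 cells - 1 (sum constraint) - 1 (estimated allele frequency)


class MonomorphicDataError(ValueError):
    """All sampled alleles identical; no HWE test is defined."""


@dataclass
class FamilyTypeCounts:
    """Weighted and raw familial-type counts of a sample of trios."""

    J_w: np.ndarray  # (10,) weighted counts
    J_raw: np.ndarray  # (10,) unweighted counts
    T_w: float  # total weighted count

    def __post_init__(self) -> None:
        if self.T_w <= 0:
            raise ValueError("total weighted count must be positive")


@dataclass
class CcsComponents:
    """Intermediate quantities of the corrected chi-square machinery."""

    p_hat_Aw: float
    pi_hat: np.ndarray
    theta: np.ndarray
    M: np.ndarray
    Sigma_hat: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    lambda_bar: float | None = None
    b2: float | None = None


def weighted_family_counts(data: FamilyData) -> FamilyTypeCounts:
    """Weighted (sum of family weights) and raw counts per familial type."""
    types0 = data.family_type - 1
    J_w = np.bincount(types0, weights=data.family_weight, minlength=N_TYPES)
    J_raw = np.bincount(types0, minlength=N_TYPES).astype(float)
    return FamilyTypeCounts(J_w=J_w, J_raw=J_raw, T_w=float(J_w.sum()))


def weighted_allele_freq(counts: FamilyTypeCounts) -> float:
    """Weighted allele-A frequency from parental genotypes.

    p_hat = c^T J_w / (4 T_w) with c the per-type count of parental A
    alleles, (4,3,3,2,2,2,2,1,1,0): the HWE maximum-likelihood estimator
    from trio data (the Mendelian child adds no information given the
    parents) and the only linear estimator symmetric under allele
    relabeling.
    """
    return float(PARENTAL_ALLELE_COUNT @ counts.J_w / (4.0 * counts.T_w))


def _components(counts: FamilyTypeCounts) -> CcsComponents:
    p_hat = weighted_allele_freq(counts)
    if not 0.0 < p_hat < 1.0:
        raise MonomorphicDataError(
            f"weighted allele frequency {p_hat}: data are monomorphic"
        )
    pi_hat = trio_type_probabilities(p_hat)
    theta = counts.J_w - counts.T_w * pi_hat
    M = np.diag(1.0 / (counts.T_w * pi_hat))
    return CcsComponents(p_hat_Aw=p_hat, pi_hat=pi_hat, theta=theta, M=M)


def naive_weighted_chisq(counts: FamilyTypeCounts) -> TestResult:
    """Uncorrected weighted Pearson chi-square against chi-square(8).

    The benchmark statistic: valid for a self-weighting simple random
    sample of independent families, anticonservative (or worse) otherwise.
    """
    comp = _components(counts)
    stat = float(comp.theta @ comp.M @ comp.theta)
    return TestResult(
        method="chisq_naive",
        statistic=stat,
        df1=DF_FULL,
        df2=None,
        p_value=float(stats.chi2.sf(stat, DF_FULL)),
        diagnostics={"p_hat_Aw": comp.p_hat_Aw, "components": comp},
    )


def taylor_cov_theta(
    data: FamilyData, design: SurveyDesign, comp: CcsComponents
) -> np.ndarray:
    """Taylor-linearization covariance of theta = J_w - T_w pi(p_hat).

    theta is a smooth function of the weighted count vector; its Jacobian is

        G = I - pi_hat 1^T - T_w (d pi/d p) (d p_hat/d J_w)^T,
        d p_hat / d J_lw = (c_l - 4 p_hat) / (4 T_w),

    so the per-family linearized variate is ``z = G (w e)`` with ``e`` the
    type indicator.  PSU totals of ``z`` are stratum-centered and combined
    with the with-replacement first-stage estimator.  Both ``1`` and ``c``
    are annihilated by ``G``, so the result has rank at most 8.
    """
    c = PARENTAL_ALLELE_COUNT
    dp_dJ = (c - 4.0 * comp.p_hat_Aw) / (4.0 * sum_w(data))
    dpi_dp = trio_type_prob_derivative(comp.p_hat_Aw)
    G = (
        np.eye(N_TYPES)
        - np.outer(comp.pi_hat, np.ones(N_TYPES))
        - sum_w(data) * np.outer(dpi_dp, dp_dJ)
    )
    e = np.zeros((data.n_families, N_TYPES))
    e[np.arange(data.n_families), data.family_type - 1] = data.family_weight
    z = e @ G.T
    return design.stratified_psu_cov(z)


def sum_w(data: FamilyData) -> float:
    return float(data.family_weight.sum())


def rao_scott_tests(
    naive: TestResult,
    Sigma_hat: np.ndarray,
    M: np.ndarray,
    design: SurveyDesign,
) -> tuple[TestResult, TestResult, TestResult]:
    """First-order, second-order and F-version Rao-Scott corrections.

    The eight algebraically largest real eigenvalue parts of ``Sigma_hat M``
    are the generalized design effects; the two remaining eigenvalues lie in
    the annihilated directions and should be numerically zero (a warning is
    emitted otherwise).
    """
    comp: CcsComponents = naive.diagnostics["components"]
    eigs = np.linalg.eigvals(Sigma_hat @ M)
    if not np.all(np.isfinite(eigs)):
        raise ValueError("non-finite eigenvalues of Sigma_hat @ M")
    real = np.sort(eigs.real)[::-1]
    lambdas, discarded = real[:DF_FULL], real[DF_FULL:]
    lambda_bar = float(lambdas.mean())
    if lambda_bar <= 0:
        raise ValueError(f"mean eigenvalue {lambda_bar} <= 0: degenerate sample")
    if np.any(np.abs(discarded) > 1e-6 * lambda_bar):
        warnings.warn(
            "discarded eigenvalues of Sigma_hat M are not numerically zero; "
            "the design covariance may not satisfy the residual constraints",
            stacklevel=2,
        )
    b2 = float(np.mean((lambdas - lambda_bar) ** 2) / lambda_bar**2)
    comp.Sigma_hat, comp.lambdas, comp.lambda_bar, comp.b2 = (
        Sigma_hat,
        lambdas,
        lambda_bar,
        b2,
    )
    diag = {
        "p_hat_Aw": comp.p_hat_Aw,
        "lambda_bar": lambda_bar,
        "b2": b2,
        "components": comp,
    }

    stat1 = naive.statistic / lambda_bar
    first = TestResult(
        "chisq_rs1", stat1, DF_FULL, None,
        float(stats.chi2.sf(stat1, DF_FULL)), dict(diag),
    )
    df2nd = DF_FULL / (1.0 + b2)
    stat2 = stat1 / (1.0 + b2)
    second = TestResult(
        "chisq_rs2", stat2, df2nd, None,
        float(stats.chi2.sf(stat2, df2nd)), dict(diag),
    )
    df_den = design.U - design.H
    statf = stat2 / df2nd
    f_version = TestResult(
        "chisq_rs2_F", statf, df2nd, df_den,
        float(stats.f.sf(statf, df2nd, df_den)), dict(diag),
    )
    return first, second, f_version


def ccs_test_suite(
    data: FamilyData, design: SurveyDesign | None = None
) -> dict[str, TestResult]:
    """All four corrected-chi-square-family tests on one sample of trios.

    Returns a dict keyed by method name: the naive weighted chi-square and
    the three Rao-Scott corrections.
    """
    if design is None:
        design = SurveyDesign.from_family_data(data)
    counts = weighted_family_counts(data)
    naive = naive_weighted_chisq(counts)
    comp = naive.diagnostics["components"]
    Sigma_hat = taylor_cov_theta(data, design, comp)
    first, second, f_version = rao_scott_tests(naive, Sigma_hat, comp.M, design)
    return {t.method: t for t in (naive, first, second, f_version)}
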