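"""Quasi-score test of Hardy-Weinberg equilibrium (H0: r = 0) from
quasi-generalized estimating equations on trio genotype indicators.

Each individual contributes the indicator pair ``y = (1{AA}, 1{Aa})`` with
mean model

    mu_AA = (1-r) p^2 + r p,   mu_Aa = 2 (1-r) p (1-p),

parameters ``theta = (p, r)``.  The estimating equations sum, over families,

    S(theta) = sum_hij  D^T W^{1/2} Var(y_hij)^{-1} W^{1/2} (y_hij - mu_hij)

where ``D`` stacks the per-member 2x2 derivative of the mean in theta and
``Var(y_hij)`` is the 6x6 genotype covariance of the trio built from
pairwise-relationship blocks (parent-offspring kinship; spouses independent
under random mating), evaluated at the null.  The test fixes ``r = 0``,
solves the p-equation for the null allele frequency ``p_tilde``, and refers

    QS = S_r(theta_tilde)^2 / V_L

to F(1, U - H), the scalar case of a Hotelling T^2 with U - H denominator
degrees of freedom (U sampled PSUs in H strata).  ``V_L`` is a design-based
linearization variance of the effective r-score: the p-direction is
projected out of each family's score contribution using the aggregated
sensitivity matrix, and PSU totals of the resulting variate are
stratum-centered as usual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .families import FamilyData, SurveyDesign
from .results import TestResult

_ARRANGEMENTS = ("pairwise", "literal")


class ConvergenceError(RuntimeError):
    """Null allele-frequency estimating equation failed to converge."""


@dataclass
class QsParameters:
    """Null-restricted parameter point: allele frequency with r fixed at 0."""

    p_tilde: float
    r: float = 0.0


def mean_vector(p: float, r: float) -> np.ndarray:
    """Per-individual expected indicators (mu_AA, mu_Aa)."""
    return np.array([(1 - r) * p * p + r * p, 2 * (1 - r) * p * (1 - p)])


def dmu_dtheta(p: float, r: float) -> np.ndarray:
    """2x2 Jacobian of (mu_AA, mu_Aa) in (p, r); rows are indicators."""
    return np.array(
        [
            [2 * (1 - r) * p + r, p * (1 - p)],
            [2 * (1 - r) * (1 - 2 * p), -2 * p * (1 - p)],
        ]
    )


def self_cov(p: float) -> np.ndarray:
    """2x2 covariance of one individual's (1{AA}, 1{Aa}) under HWE."""
    q = 1.0 - p
    return np.array(
        [
            [p * p * (1 - p * p), -2 * p**3 * q],
            [-2 * p**3 * q, 2 * p * q * (1 - 2 * p * q)],
        ]
    )


def parent_offspring_cov(p: float) -> np.ndarray:
    """2x2 cross-covariance of a parent's and their child's indicators under HWE.

    The child shares exactly one allele identical by descent with each
    parent, e.g. Cov(1{AA_parent}, 1{AA_child}) = p^3 (1-p).
    """
    q = 1.0 - p
    return np.array(
        [
            [p**3 * q, p * p * q * (1 - 2 * p)],
            [p * p * q * (1 - 2 * p), p * q * (1 - 4 * p * q)],
        ]
    )


def full_sib_cov(p: float) -> np.ndarray:
    """2x2 cross-covariance for a full-sib pair under HWE.

    Sibs share 0/1/2 alleles identical by descent with probabilities
    1/4, 1/2, 1/4; sharing two alleles makes the genotypes identical,
    sharing one reproduces the parent-offspring structure, sharing none
    gives independence, so the block is exactly
    ``1/4 Sigma_self + 1/2 Sigma_PO`` — e.g. the (AA, AA) entry is
    p^2/4 + p^3/2 - 3 p^4/4 and the (Aa, Aa) entry pq(1 - 3pq).
    Not used for a trio under the pairwise arrangement; kept for the
    sensitivity arrangement and for other family shapes.
    """
    return 0.25 * self_cov(p) + 0.5 * parent_offspring_cov(p)


def trio_covariance(p: float, arrangement: str = "pairwise") -> np.ndarray:
    """6x6 Var(y) of a trio's stacked indicators at r = 0.

    ``pairwise`` (default) assigns blocks by actual relationship for members
    ordered (father, mother, child): spouse block zero under random mating,
    parent-child blocks from the parent-offspring kinship.  ``literal``
    reproduces a one-parent/two-offspring arrangement (parent-offspring
    blocks off the first member, a full-sib block between the last two),
    retained for sensitivity analysis.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency {p} on the boundary")
    if arrangement not in _ARRANGEMENTS:
        raise ValueError(f"arrangement must be one of {_ARRANGEMENTS}")
    S = self_cov(p)
    PO = parent_offspring_cov(p)
    V = np.zeros((6, 6))
    for k in range(3):
        V[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = S
    if arrangement == "pairwise":
        blocks = {(0, 2): PO, (1, 2): PO}  # father-child, mother-child
    else:
        blocks = {(0, 1): PO, (0, 2): PO, (1, 2): full_sib_cov(p)}
    for (i, j), B in blocks.items():
        V[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = B
        V[2 * j : 2 * j + 2, 2 * i : 2 * i + 2] = B.T
    return V


def indicator_matrix(genotypes: np.ndarray) -> np.ndarray:
    """(n, 6) stacked (1{AA}, 1{Aa}) indicators for (father, mother, child)."""
    g = np.asarray(genotypes)
    y = np.zeros((g.shape[0], 6))
    for k in range(3):
        y[:, 2 * k] = g[:, k] == 0
        y[:, 2 * k + 1] = g[:, k] == 1
    return y


def _family_system(p: float, r: float, arrangement: str):
    """Shared per-family quantities: mu (6,), D (6, 2), B = D^T V^{-1} (2, 6).

    With family-level weights every member of a family carries the same
    weight, so ``W^{1/2} V^{-1} W^{1/2} = w V^{-1}`` and the family system
    is identical across families up to the scalar weight.
    """
    mu = np.tile(mean_vector(p, r), 3)
    D = np.tile(dmu_dtheta(p, r), (3, 1))
    V = trio_covariance(p, arrangement)
    B = np.linalg.solve(V, D).T  # (2, 6)
    return mu, D, B


def _score(p: float, data: FamilyData, y: np.ndarray, arrangement: str):
    """Total score (S_p, S_r) at (p, 0) plus the shared system."""
    mu, D, B = _family_system(p, 0.0, arrangement)
    resid = (y - mu) * data.family_weight[:, None]
    S = B @ resid.sum(axis=0)
    return S, mu, D, B


def solve_null_allele_freq(
    data: FamilyData, arrangement: str = "pairwise", tol: float = 1e-10,
    max_iter: int = 50,
) -> QsParameters:
    """Solve the p-component of the estimating equations with r fixed at 0.

    Newton iteration with a finite-difference slope and step halving,
    started at the weighted sample allele frequency; convergence when
    |S_p| < tol * (total family weight).  Falls back to bracketed root
    finding if Newton stalls.
    """
    y = indicator_matrix(data.genotypes)
    w_tot = float(data.family_weight.sum())
    scale = tol * w_tot

    def s_p(p: float) -> float:
        return float(_score(p, data, y, arrangement)[0][0])

    # weighted allele frequency over all 3 members as the starting value
    g = data.genotypes.astype(float)
    p0 = float(
        ((2.0 - g) * data.member_weights).sum() / (2.0 * data.member_weights.sum())
    )
    if not 0.0 < p0 < 1.0:
        raise MonomorphicSampleError(f"sample allele frequency {p0} on the boundary")
    eps = 1e-9
    p = min(max(p0, eps), 1 - eps)
    f = s_p(p)
    for _ in range(max_iter):
        if abs(f) < scale:
            return QsParameters(p_tilde=p)
        h = 1e-6
        slope = (s_p(min(p + h, 1 - eps)) - s_p(max(p - h, eps))) / (
            min(p + h, 1 - eps) - max(p - h, eps)
        )
        if slope == 0.0:
            break
        step = -f / slope
        for _ in range(30):  # step halving
            cand = min(max(p + step, eps), 1 - eps)
            fc = s_p(cand)
            if abs(fc) < abs(f) or abs(fc) < scale:
                p, f = cand, fc
                break
            step *= 0.5
        else:
            break
    # bracketed fallback
    try:
        root = optimize.brentq(s_p, eps, 1 - eps, xtol=1e-14)
    except ValueError as exc:  # no sign change: degenerate sample
        raise ConvergenceError(
            f"null score equation did not converge (last |S_p|={abs(f):.3g})"
        ) from exc
    if abs(s_p(root)) >= scale * 10:
        raise ConvergenceError("null score equation did not converge")
    return QsParameters(p_tilde=float(root))


class MonomorphicSampleError(ValueError):
    """Sample carries only one allele; the null model is on the boundary."""


def score_contributions(
    data: FamilyData, params: QsParameters, arrangement: str = "pairwise"
):
    """Per-family score contributions and aggregated sensitivity at the null.

    Returns ``(s, A)``: ``s`` is (n, 2) with columns (s_p, s_r) and ``A`` the
    2x2 model-based sensitivity ``sum_hij w D^T V^{-1} D``.
    """
    y = indicator_matrix(data.genotypes)
    mu, D, B = _family_system(params.p_tilde, params.r, arrangement)
    resid = (y - mu) * data.family_weight[:, None]
    s = resid @ B.T  # (n, 2)
    A = float(data.family_weight.sum()) * (B @ D)
    return s, A


def variance_score_r(
    s: np.ndarray, A: np.ndarray, design: SurveyDesign
) -> float:
    """Design-based linearization variance of the effective r-score.

    The nuisance direction is projected out family by family,
    ``u = s_r - (A_rp / A_pp) s_p``, and the with-replacement stratified
    PSU-total variance of ``u`` is returned.
    """
    u = s[:, 1] - (A[1, 0] / A[0, 0]) * s[:, 0]
    V_L = float(design.stratified_psu_cov(u[:, None])[0, 0])
    if V_L <= 0:
        raise ValueError("degenerate sample: estimated score variance <= 0")
    return V_L


def qs_test(
    data: FamilyData,
    design: SurveyDesign | None = None,
    arrangement: str = "pairwise",
) -> TestResult:
    """Quasi-score test of HWE (r = 0) with design-based variance.

    ``QS = S_r(theta_tilde)^2 / V_L`` referred to F(1, U - H).
    """
    if design is None:
        design = SurveyDesign.from_family_data(data)
    design.require_replicable_variance()
    params = solve_null_allele_freq(data, arrangement)
    s, A = score_contributions(data, params, arrangement)
    S_r = float(s[:, 1].sum())
    V_L = variance_score_r(s, A, design)
    stat = S_r * S_r / V_L
    df2 = design.U - design.H
    return TestResult(
        method="qs",
        statistic=stat,
        df1=1.0,
        df2=float(df2),
        p_value=float(stats.f.sf(stat, 1, df2)),
        diagnostics={
            "p_tilde": params.p_tilde,
            "S_r": S_r,
            "V_L": V_L,
            "arrangement": arrangement,
        },
    )
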