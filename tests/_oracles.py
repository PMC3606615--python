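"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (explicit loops, full enumeration)
and shares no code path with the production implementations it checks.
"""

from __future__ import annotations

import numpy as np

# transmission probability of allele a for genotype code 0,1,2 (AA, Aa, aa)
_TRANSMIT_A = {0: 0.0, 1: 0.5, 2: 1.0}

# row of the ten-type table for each (unordered parents, child) combination
_TYPE_TABLE = {
    ((0, 0), 0): 1,
    ((0, 1), 0): 2,
    ((0, 1), 1): 3,
    ((0, 2), 1): 4,
    ((1, 1), 0): 5,
    ((1, 1), 1): 6,
    ((1, 1), 2): 7,
    ((1, 2), 1): 8,
    ((1, 2), 2): 9,
    ((2, 2), 2): 10,
}


def genotype_probs(p: float, r: float) -> list[float]:
    q = 1.0 - p
    return [(1 - r) * p * p + r * p, 2 * (1 - r) * p * q, (1 - r) * q * q + r * q]


def child_probs(gf: int, gm: int) -> list[float]:
    """Child genotype distribution by enumerating the four allele pairs."""
    out = [0.0, 0.0, 0.0]
    for af in (0, 1):  # 1 = transmits allele a
        for am in (0, 1):
            pf = _TRANSMIT_A[gf] if af else 1 - _TRANSMIT_A[gf]
            pm = _TRANSMIT_A[gm] if am else 1 - _TRANSMIT_A[gm]
            out[af + am] += pf * pm
    return out


def enumerate_type_distribution(p: float, r: float = 0.0) -> np.ndarray:
    """Ten-type probabilities by full 3x3x3 enumeration of trios."""
    pi = np.zeros(10)
    gp = genotype_probs(p, r)
    for gf in range(3):
        for gm in range(3):
            cp = child_probs(gf, gm)
            for gc in range(3):
                key = (tuple(sorted((gf, gm))), gc)
                if cp[gc] > 0:
                    pi[_TYPE_TABLE[key] - 1] += gp[gf] * gp[gm] * cp[gc]
    return pi


def enumerate_mendelian_trios() -> list[tuple[int, int, int]]:
    """All (gf, gm, gc) with positive probability under Mendelian transmission."""
    return [
        (gf, gm, gc)
        for gf in range(3)
        for gm in range(3)
        for gc in range(3)
        if child_probs(gf, gm)[gc] > 0
    ]


def pearson_sum(J_w: np.ndarray, expected: np.ndarray) -> float:
    """Plain sum (O - E)^2 / E over the ten cells."""
    total = 0.0
    for o, e in zip(J_w, expected):
        total += (o - e) ** 2 / e
    return total


def pair_indicator_cov(joint, marg1, marg2) -> np.ndarray:
    """2x2 covariance of (1{AA},1{Aa}) pairs from a joint 3x3 distribution."""
    cov = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            p_joint = joint[i, j]
            cov[i, j] = p_joint - marg1[i] * marg2[j]
    return cov


def parent_child_joint(p: float) -> np.ndarray:
    """3x3 joint genotype distribution of one HWE parent and its child.

    The other parent is integrated out over HWE.
    """
    gp = genotype_probs(p, 0.0)
    joint = np.zeros((3, 3))
    for g1 in range(3):
        for g2 in range(3):
            cp = child_probs(g1, g2)
            for gc in range(3):
                joint[g1, gc] += gp[g1] * gp[g2] * cp[gc]
    return joint


def sib_joint(p: float) -> np.ndarray:
    """3x3 joint genotype distribution of two full sibs under HWE parents."""
    gp = genotype_probs(p, 0.0)
    joint = np.zeros((3, 3))
    for g1 in range(3):
        for g2 in range(3):
            cp = child_probs(g1, g2)
            pp = gp[g1] * gp[g2]
            for c1 in range(3):
                for c2 in range(3):
                    joint[c1, c2] += pp * cp[c1] * cp[c2]
    return joint


def jackknife_psu_cov(values: np.ndarray, psu_index: np.ndarray) -> np.ndarray:
    """Delete-one-PSU jackknife covariance of a total (single stratum).

    values: (n, k) per-family linearized rows; the statistic is the total.
    """
    U = psu_index.max() + 1
    totals = np.zeros((U, values.shape[1]))
    np.add.at(totals, psu_index, values)
    grand = totals.sum(axis=0)
    k = values.shape[1]
    cov = np.zeros((k, k))
    for u in range(U):
        # replicate estimate: total scaled up from the remaining U-1 PSUs
        rep = (grand - totals[u]) * U / (U - 1)
        d = rep - grand
        cov += np.outer(d, d)
    return cov * (U - 1) / U


def icc_anova(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation for equal-size groups."""
    uniq = np.unique(groups)
    k = len(values) // len(uniq)
    means = np.array([values[groups == g].mean() for g in uniq])
    msb = k * np.sum((means - values.mean()) ** 2) / (len(uniq) - 1)
    msw = sum(
        np.sum((values[groups == g] - values[groups == g].mean()) ** 2)
        for g in uniq
    ) / (len(values) - len(uniq))
    return float((msb - msw) / (msb + (k - 1) * msw))
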