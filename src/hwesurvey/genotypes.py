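"""Biallelic genotype model with a fixation index, Mendelian transmission,
and the ten familial types of a parents-child trio.

Genotypes at a diallelic autosomal locus (alleles ``A`` and ``a``) are coded
as fixed integers throughout the package::

    AA = 0,  Aa = 1,  aa = 2

i.e. the code is the number of copies of allele ``a``.  The fixation index
``r`` is the correlation between the two alleles carried by one individual;
``r = 0`` is Hardy-Weinberg equilibrium (HWE) and the genotype frequencies
are

    P(AA) = (1-r) p_A^2 + r p_A
    P(Aa) = 2 (1-r) p_A p_a
    P(aa) = (1-r) p_a^2 + r p_a

with ``p_a = 1 - p_A``.  Negative ``r`` (heterozygote excess) is admissible
down to ``-min(p_A/p_a, p_a/p_A)``, the point where a genotype frequency
hits zero.

A trio (father, mother, child) with a Mendelian child falls into one of ten
familial types once the ordering of the parents is ignored; under HWE the
type probabilities are polynomials in ``p_A`` and the vector of weighted
type counts is the input to the corrected chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AA: int = 0
Aa: int = 1
aa: int = 2

GENOTYPE_LABELS: tuple[str, str, str] = ("AA", "Aa", "aa")

#: number of A alleles carried by the two parents, per familial type 1..10
PARENTAL_ALLELE_COUNT = np.array([4, 3, 3, 2, 2, 2, 2, 1, 1, 0], dtype=float)

#: familial type polynomial coefficients: pi_l = k * p_A**a * p_a**b
_TYPE_POLY = np.array(
    [  # k, a, b
        (1, 4, 0),
        (2, 3, 1),
        (2, 3, 1),
        (2, 2, 2),
        (1, 2, 2),
        (2, 2, 2),
        (1, 2, 2),
        (2, 1, 3),
        (2, 1, 3),
        (1, 0, 4),
    ],
    dtype=float,
)

# P(transmit A), P(transmit a) for parent genotype 0,1,2
_TRANSMIT = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])


class MendelianError(ValueError):
    """A trio whose child cannot have inherited its alleles from its parents."""


def _build_type_lookup() -> np.ndarray:
    """(gf, gm, gc) -> familial type 1..10, or -1 for Mendelian-impossible."""
    # unordered parental pair -> {child genotype -> type}
    table = {
        (AA, AA): {AA: 1},
        (AA, Aa): {AA: 2, Aa: 3},
        (AA, aa): {Aa: 4},
        (Aa, Aa): {AA: 5, Aa: 6, aa: 7},
        (Aa, aa): {Aa: 8, aa: 9},
        (aa, aa): {aa: 10},
    }
    lut = np.full((3, 3, 3), -1, dtype=np.int8)
    for gf in (AA, Aa, aa):
        for gm in (AA, Aa, aa):
            pair = (min(gf, gm), max(gf, gm))
            for gc, t in table[pair].items():
                lut[gf, gm, gc] = t
    return lut


_TYPE_LOOKUP = _build_type_lookup()


@dataclass(frozen=True)
class GenotypeModel:
    """Allele-A frequency and fixation index for one locus.

    Raises ``ValueError`` if the pair does not yield a valid genotype
    distribution (all three frequencies in [0, 1]).
    """

    p_A: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_A <= 1.0:
            raise ValueError(f"allele frequency p_A={self.p_A} outside [0, 1]")
        r_min = _r_lower_bound(self.p_A)
        if not r_min <= self.r <= 1.0:
            raise ValueError(
                f"fixation index r={self.r} outside [{r_min:.6g}, 1] for p_A={self.p_A}"
            )

    @property
    def p_a(self) -> float:
        return 1.0 - self.p_A


def _r_lower_bound(p_A: float) -> float:
    p_a = 1.0 - p_A
    if p_A == 0.0 or p_a == 0.0:
        return 0.0
    return -min(p_A / p_a, p_a / p_A)


def genotype_distribution(model: GenotypeModel) -> np.ndarray:
    """Genotype frequencies (P(AA), P(Aa), P(aa)) under the fixation-index model."""
    p, q, r = model.p_A, model.p_a, model.r
    return np.array(
        [(1 - r) * p * p + r * p, 2 * (1 - r) * p * q, (1 - r) * q * q + r * q]
    )


def mendelian_child_distribution(gf: int, gm: int) -> np.ndarray:
    """Child genotype distribution given parental genotypes.

    Each parent transmits one of its two alleles uniformly at random; the
    child distribution is the convolution of the two transmission laws.
    """
    tf, tm = _TRANSMIT[gf], _TRANSMIT[gm]
    return np.array(
        [tf[0] * tm[0], tf[0] * tm[1] + tf[1] * tm[0], tf[1] * tm[1]]
    )


def classify_trio(gf: int, gm: int, gc: int) -> int:
    """Familial type (1..10) of a trio, ignoring the order of the parents."""
    t = int(_TYPE_LOOKUP[gf, gm, gc])
    if t < 0:
        raise MendelianError(
            f"child {GENOTYPE_LABELS[gc]} impossible for parents "
            f"{GENOTYPE_LABELS[gf]} x {GENOTYPE_LABELS[gm]}"
        )
    return t


def classify_trios(genotypes: np.ndarray) -> np.ndarray:
    """Vectorized familial-type classification.

    Parameters
    ----------
    genotypes : (n, 3) integer array of (father, mother, child) codes.

    Returns
    -------
    (n,) array of types in 1..10.  Raises :class:`MendelianError` listing the
    offending rows if any trio is Mendelian-impossible.
    """
    g = np.asarray(genotypes)
    types = _TYPE_LOOKUP[g[:, 0], g[:, 1], g[:, 2]]
    bad = np.flatnonzero(types < 0)
    if bad.size:
        head = ", ".join(str(int(i)) for i in bad[:10])
        raise MendelianError(
            f"{bad.size} Mendelian-inconsistent trio(s) at row index(es) {head}"
        )
    return types.astype(np.int64)


def trio_type_probabilities(p_A: float) -> np.ndarray:
    """Joint probabilities of the 10 familial types under HWE.

    pi = (p^4, 2p^3 q, 2p^3 q, 2p^2 q^2, p^2 q^2, 2p^2 q^2, p^2 q^2,
          2p q^3, 2p q^3, q^4) with q = 1 - p_A; sums to 1 for any p_A.
    """
    if not 0.0 <= p_A <= 1.0:
        raise ValueError(f"p_A={p_A} outside [0, 1]")
    q = 1.0 - p_A
    k, a, b = _TYPE_POLY.T
    return k * p_A**a * q**b


def trio_type_prob_derivative(p_A: float) -> np.ndarray:
    """d pi / d p_A, the gradient of the type probabilities in the allele frequency."""
    q = 1.0 - p_A
    k, a, b = _TYPE_POLY.T
    with np.errstate(divide="ignore", invalid="ignore"):
        da = np.where(a > 0, a * p_A ** np.maximum(a - 1, 0) * q**b, 0.0)
        db = np.where(b > 0, b * p_A**a * q ** np.maximum(b - 1, 0), 0.0)
    return k * (da - db)
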