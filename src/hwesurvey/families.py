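"""Containers for sampled trio families and the survey design behind them.

The analysis modules work on a column-oriented :class:`FamilyData` (numpy
arrays over families) because the Monte-Carlo studies touch millions of
trios; :class:`TrioFamily` is the scalar record used by the table reader and
writer.  :class:`SurveyDesign` captures the stratum/PSU structure every
design-based variance estimator needs: variances are estimated from the
between-PSU spread of PSU totals within each stratum, which requires at
least two sampled PSUs per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import classify_trios


class DesignError(ValueError):
    """Survey design unusable for variance estimation (e.g. singleton-PSU stratum)."""


@dataclass(frozen=True)
class TrioFamily:
    """One sampled two-parent/one-child family with design identifiers."""

    stratum_id: int
    psu_id: int
    family_id: int
    genotypes: tuple[int, int, int]  # (father, mother, child) codes
    member_weights: tuple[float, float, float]
    family_weight: float

    def __post_init__(self) -> None:
        if self.family_weight <= 0 or any(w <= 0 for w in self.member_weights):
            raise ValueError(
                f"family {self.family_id}: weights must be positive"
            )


class FamilyData:
    """Column-oriented collection of sampled trio families.

    Parameters
    ----------
    stratum, psu, family_id : (n,) integer identifier arrays.
    genotypes : (n, 3) integer codes for (father, mother, child).
    family_weight : (n,) positive family-level sampling weights.
    member_weights : optional (n, 3) member-level weights; defaults to the
        family weight repeated over the trio.

    Mendelian consistency of every trio is validated on construction and the
    familial type (1..10) of each family is cached in ``family_type``.
    """

    def __init__(
        self,
        stratum: np.ndarray,
        psu: np.ndarray,
        family_id: np.ndarray,
        genotypes: np.ndarray,
        family_weight: np.ndarray,
        member_weights: np.ndarray | None = None,
    ) -> None:
        n = len(family_id)
        if n == 0:
            raise ValueError("empty family collection")
        self.stratum = np.asarray(stratum, dtype=np.int64)
        self.psu = np.asarray(psu, dtype=np.int64)
        self.family_id = np.asarray(family_id, dtype=np.int64)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.family_weight = np.asarray(family_weight, dtype=float)
        if self.genotypes.shape != (n, 3):
            raise ValueError("genotypes must have shape (n, 3)")
        if np.any(self.family_weight <= 0):
            raise ValueError("family weights must be positive")
        if member_weights is None:
            member_weights = np.repeat(self.family_weight[:, None], 3, axis=1)
        self.member_weights = np.asarray(member_weights, dtype=float)
        if np.any(self.member_weights <= 0):
            raise ValueError("member weights must be positive")
        self.family_type = classify_trios(self.genotypes)  # validates Mendel

    @property
    def n_families(self) -> int:
        return len(self.family_id)

    def with_weights(
        self,
        family_weight: np.ndarray,
        member_weights: np.ndarray | None = None,
    ) -> "FamilyData":
        return FamilyData(
            self.stratum,
            self.psu,
            self.family_id,
            self.genotypes,
            family_weight,
            member_weights,
        )

    def to_records(self) -> list[TrioFamily]:
        return [
            TrioFamily(
                int(self.stratum[i]),
                int(self.psu[i]),
                int(self.family_id[i]),
                tuple(int(g) for g in self.genotypes[i]),
                tuple(float(w) for w in self.member_weights[i]),
                float(self.family_weight[i]),
            )
            for i in range(self.n_families)
        ]

    @classmethod
    def from_records(cls, records: list[TrioFamily]) -> "FamilyData":
        return cls(
            np.array([f.stratum_id for f in records]),
            np.array([f.psu_id for f in records]),
            np.array([f.family_id for f in records]),
            np.array([f.genotypes for f in records]),
            np.array([f.family_weight for f in records]),
            np.array([f.member_weights for f in records]),
        )


@dataclass
class SurveyDesign:
    """Stratum/PSU structure of a sample of families.

    ``psu_index`` maps each family to a row of the PSU list; ``psu_stratum``
    gives the stratum index of each PSU.  ``U`` is the total number of
    sampled PSUs and ``H`` the number of strata, so design-based chi-square
    and F references use ``U - H`` denominator degrees of freedom.
    """

    psu_index: np.ndarray  # (n_families,) index into the distinct-PSU list
    psu_stratum: np.ndarray  # (U,) stratum index of each distinct PSU
    H: int
    U: int
    I_h: np.ndarray = field(default=None)  # (H,) PSUs per stratum

    def __post_init__(self) -> None:
        if self.I_h is None:
            self.I_h = np.bincount(self.psu_stratum, minlength=self.H)

    @classmethod
    def from_family_data(cls, data: FamilyData) -> "SurveyDesign":
        keys = data.stratum.astype(np.int64) * (data.psu.max() + 1) + data.psu
        _, first, psu_index = np.unique(keys, return_index=True, return_inverse=True)
        psu_strata_raw = data.stratum[first]
        strata, psu_stratum = np.unique(psu_strata_raw, return_inverse=True)
        return cls(
            psu_index=psu_index,
            psu_stratum=psu_stratum,
            H=len(strata),
            U=len(psu_stratum),
        )

    def require_replicable_variance(self) -> None:
        bad = np.flatnonzero(self.I_h < 2)
        if bad.size:
            raise DesignError(
                f"stratum index(es) {bad.tolist()} contain a single sampled PSU; "
                "variance estimation needs >=2 PSUs per stratum "
                "(collapse or combine strata first)"
            )

    def psu_totals(self, values: np.ndarray) -> np.ndarray:
        """Sum per-family rows of ``values`` (n, k) into PSU totals (U, k)."""
        v = np.atleast_2d(np.asarray(values, dtype=float).T).T
        out = np.zeros((self.U, v.shape[1]))
        np.add.at(out, self.psu_index, v)
        return out

    def stratified_psu_cov(self, values: np.ndarray) -> np.ndarray:
        """Design-based covariance of a total from per-family linearized rows.

        With-replacement first-stage approximation: PSU totals ``z_hi`` are
        centered within each stratum and
        ``Cov = sum_h I_h/(I_h-1) sum_i (z_hi - zbar_h)(z_hi - zbar_h)^T``.
        """
        self.require_replicable_variance()
        z = self.psu_totals(values)  # (U, k)
        k = z.shape[1]
        cov = np.zeros((k, k))
        for h in range(self.H):
            rows = z[self.psu_stratum == h]
            Ih = rows.shape[0]
            d = rows - rows.mean(axis=0)
            cov += (Ih / (Ih - 1.0)) * d.T @ d
        return cov
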