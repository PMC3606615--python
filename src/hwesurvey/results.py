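"""Common result record for all five HWE test statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any


@dataclass
class TestResult:
    """Outcome of one test: statistic, reference distribution, p-value.

    ``df1`` may be fractional (Satterthwaite-type corrections); ``df2`` is
    the denominator degrees of freedom of an F reference, or ``None`` for a
    chi-square reference.  ``diagnostics`` carries method-specific quantities
    (eigenvalue mean, dispersion, estimated allele frequency, score variance).
    """

    __test__ = False  # not a pytest class despite the name

    method: str
    statistic: float
    df1: float
    df2: float | None
    p_value: float
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def row(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df1": self.df1,
            "df2": self.df2 if self.df2 is not None else float("nan"),
            "p_value": self.p_value,
        }
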