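"""Two-sample test for equality of proportions with Yates' correction.

The matching experiments are compared with the classic 2x2 chi-square
test on success counts x1/n1 vs x2/n2, with the continuity correction
chi2 = N (max(|ad - bc| - N/2, 0))^2 / (r1 r2 c1 c2) on the table
a = x1, b = n1 - x1, c = x2, d = n2 - x2, referred to the 1-df
chi-square upper tail (two-sided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    chi2: float
    p_value: float
    corrected: bool = True

    @property
    def proportions(self) -> tuple[float, float]:
        return self.x1 / self.n1, self.x2 / self.n2


def chi2_sf_1df(x: float) -> float:
    """Upper-tail probability of a 1-df chi-square: erfc(sqrt(x/2))."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return math.erfc(math.sqrt(x / 2.0))


def yates_prop_test(
    x1: int, n1: int, x2: int, n2: int, corrected: bool = True
) -> ProportionTestResult:
    """Compare two success proportions with Yates' continuity correction."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    n_total = n1 + n2
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        raise ValueError("test undefined: a margin of the 2x2 table is zero")
    diff = abs(a * d - b * c)
    if corrected:
        diff = max(diff - n_total / 2.0, 0.0)
    chi2 = n_total * diff**2 / (n1 * n2 * col1 * col2)
    return ProportionTestResult(
        x1=x1, n1=n1, x2=x2, n2=n2, chi2=chi2, p_value=chi2_sf_1df(chi2), corrected=corrected
    )
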