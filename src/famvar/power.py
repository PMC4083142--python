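"""Power of the two-sided paired t-test, from the noncentral t distribution.

For a paired design with n pairs and standardized effect size d (mean
paired difference over its standard deviation), the test statistic under
the alternative follows a noncentral t distribution with df = n − 1 and
noncentrality λ = d·√n.  With t* the (1 − α/2) central-t quantile,

    power = P(T′ > t*) + P(T′ < −t*),      T′ ~ t(df, λ)

The opposite-tail term is numerically negligible at moderate effect sizes
but kept for correctness.  Genetic design parameters (genetic relative
risk, disease prevalence, locus frequency, sib recurrence ratio) may be
attached as metadata for reporting; they never enter the computation — no
closed-form mapping from them to the standardized effect size is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import integrate, stats

from .variant_core import DomainError


def _nct_tail(t: float, df: int, nc: float, upper: bool) -> float:
    """Noncentral-t tail probability by direct quadrature over the
    chi-square mixing variable; used when scipy's nct implementation
    returns NaN at extreme noncentrality.

    T' = (Z + nc) / sqrt(V/df) with Z ~ N(0,1), V ~ chi2(df), so
    P(T' > t) = E_V[ Phi(nc - t*sqrt(V/df)) ].
    """
    def integrand(v: float) -> float:
        s = np.sqrt(v / df)
        if upper:
            return stats.chi2.pdf(v, df) * stats.norm.cdf(nc - t * s)
        return stats.chi2.pdf(v, df) * stats.norm.cdf(t * s - nc)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(val)


@dataclass
class PowerParams:
    effect_size: float
    n: int
    alpha: float = 0.05
    sides: str = "two_sided"  # or "one_sided"
    metadata: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError(f"need at least 2 pairs, got n={self.n}")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.sides not in ("two_sided", "one_sided"):
            raise DomainError(f"sides must be two_sided or one_sided, got {self.sides!r}")


def paired_t_power(p: PowerParams) -> float:
    """Exact power of the paired t-test at the given parameters."""
    df = p.n - 1
    nc = p.effect_size * np.sqrt(p.n)
    if p.sides == "two_sided":
        tcrit = stats.t.ppf(1.0 - p.alpha / 2.0, df)
        power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if np.isnan(power):
            power = _nct_tail(tcrit, df, nc, upper=True) + _nct_tail(
                -tcrit, df, nc, upper=False
            )
    else:
        tcrit = stats.t.ppf(1.0 - p.alpha, df)
        power = stats.nct.sf(tcrit, df, nc)
        if np.isnan(power):
            power = _nct_tail(tcrit, df, nc, upper=True)
    return float(power)


def solve_n(
    effect_size: float,
    target_power: float,
    alpha: float = 0.05,
    sides: str = "two_sided",
    n_max: int = 10_000_000,
) -> int:
    """Smallest n ≥ 2 pairs achieving the target power, by doubling
    bracket then bisection."""
    if effect_size == 0.0:
        raise DomainError("effect size 0 can never reach a power above alpha")
    if not (0.0 < target_power < 1.0):
        raise DomainError(f"target power must lie in (0,1), got {target_power}")

    def power_at(n: int) -> float:
        return paired_t_power(PowerParams(effect_size, n, alpha, sides))

    lo, hi = 2, 2
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise DomainError(
                f"target power {target_power} not reachable with n <= {n_max} "
                f"at effect size {effect_size}"
            )
    # power is monotone increasing in n, so bisect for the threshold
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return max(lo, 2)
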