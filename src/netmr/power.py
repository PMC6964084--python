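"""Analytic power for two-sample MR, mRnd-style normal approximation.

For a binary outcome analysed on the log-OR scale, the IVW estimate based on
instruments explaining a fraction R² of the exposure's variance, in an
outcome study of N subjects with case fraction K, has approximate non-centrality
sqrt(N · R² · K(1−K)) · |ln OR|.  Power at two-sided level alpha is the upper
tail of that shifted normal past z_{1−alpha/2}.  The continuous-outcome
variant replaces K(1−K)·ln²OR with the squared standardized effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "mr_power_binary", "mr_power_continuous"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the power calculation.

    n_outcome : outcome-study sample size (cases + controls for binary)
    case_fraction : K in (0,1); ignored for continuous outcomes
    r2_instrument : variance of the exposure explained by the instruments
    effect : OR for binary outcomes, standardized beta for continuous
    alpha : two-sided significance level
    """

    n_outcome: int
    r2_instrument: float
    effect: float
    case_fraction: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        if not 0 < self.r2_instrument < 1:
            raise ValueError("r2_instrument must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.case_fraction is not None and not 0 < self.case_fraction < 1:
            raise ValueError(f"case fraction must be in (0,1), got {self.case_fraction}")


def mr_power_binary(spec: PowerSpec) -> float:
    """Power to detect an odds ratio ``spec.effect`` with a binary outcome.

    power = Phi( sqrt(N·R²·K·(1−K)) · |ln OR| − z_{1−alpha/2} )

    Returned unrounded; report layers round to the 2-decimal convention of
    published power tables.  At OR = 1 this is alpha/2 (the one tail the
    |ln OR| folding keeps).
    """
    if spec.case_fraction is None:
        raise ValueError("binary-outcome power needs case_fraction")
    if spec.effect <= 0:
        raise ValueError("OR must be positive")
    k = spec.case_fraction
    z = stats.norm.ppf(1 - spec.alpha / 2)
    ncp = math.sqrt(spec.n_outcome * spec.r2_instrument * k * (1 - k)) * abs(
        math.log(spec.effect)
    )
    return float(stats.norm.cdf(ncp - z))


def mr_power_continuous(spec: PowerSpec) -> float:
    """Power for a standardized continuous outcome:
    Phi( sqrt(N·R²)·|beta| − z_{1−alpha/2} )."""
    z = stats.norm.ppf(1 - spec.alpha / 2)
    ncp = math.sqrt(spec.n_outcome * spec.r2_instrument) * abs(spec.effect)
    return float(stats.norm.cdf(ncp - z))
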