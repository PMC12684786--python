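"""Between-outcome contrasts and statistical power for binary-outcome MR.

The between-estimate Cochran Q compares the causal estimate for one outcome
against a positive control (large-artery atherosclerotic stroke here): a
two-study fixed-effect pool with 1 degree of freedom.  Printed odds ratios
with 95% CIs can be converted back to (beta, se) pairs for such desk
re-analyses.

Power follows the standard non-centrality approximation for a binary
outcome: for a causal log-odds ``b`` per exposure unit, instrument strength
``r2`` (variance of the exposure explained), sample size ``N`` and case
fraction ``K``, the test statistic is approximately normal with mean
``b * sqrt(N * r2 * K * (1-K))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .mr import Z95, MREstimate, QResult


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a binary-outcome MR power calculation."""

    n_cases: int
    n_controls: int
    r2_explained: float
    alpha: float = 0.05
    target_power: float = 0.8
    decrement_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if not 0 < self.r2_explained < 1:
            raise ValueError("r2_explained must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if self.decrement_scale == 0:
            raise ValueError("decrement_scale must be nonzero")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def estimate_from_or_ci(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (beta, se) on the log scale from a printed OR and 95% CI."""
    if not 0 < ci_low <= or_point <= ci_high:
        raise ValueError(
            f"require 0 < ci_low <= or <= ci_high, got ({ci_low}, {or_point}, {ci_high})"
        )
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if se == 0:
        warnings.warn("degenerate CI (zero width): se = 0", stacklevel=2)
    return beta, se


def between_estimate_q(a: MREstimate, b: MREstimate) -> QResult:
    """Cochran Q contrast between two estimates on the same scale (df = 1)."""
    if a.se <= 0 or b.se <= 0:
        raise ValueError("both estimates need se > 0")
    wa, wb = 1.0 / a.se**2, 1.0 / b.se**2
    pooled = (wa * a.beta + wb * b.beta) / (wa + wb)
    q = wa * (a.beta - pooled) ** 2 + wb * (b.beta - pooled) ** 2
    return QResult(q=float(q), df=1, pvalue=float(stats.chi2.sf(q, 1)))


def _noncentrality(spec: PowerSpec, b_per_unit: float) -> float:
    k = spec.case_fraction
    return b_per_unit * math.sqrt(spec.n_total * spec.r2_explained * k * (1.0 - k))


def power_at_or(spec: PowerSpec, or_per_decrement: float) -> float:
    """Power to detect a given OR per biomarker decrement at level alpha."""
    if or_per_decrement <= 0:
        raise ValueError("or_per_decrement must be > 0")
    b = abs(math.log(or_per_decrement)) / abs(spec.decrement_scale)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(_noncentrality(spec, b) - z_crit))


def min_detectable_or(spec: PowerSpec) -> float:
    """Smallest (protective-direction) OR per decrement detectable at target power."""
    k = spec.case_fraction
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_pow = stats.norm.ppf(spec.target_power)
    b_star = (z_crit + z_pow) / math.sqrt(spec.n_total * spec.r2_explained * k * (1.0 - k))
    return math.exp(-b_star * abs(spec.decrement_scale))
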