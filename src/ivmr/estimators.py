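"""Causal-effect estimation from harmonized summary statistics.

Per SNP *j* with exposure association ``(b_xj, s_xj)`` and outcome
association ``(b_yj, s_yj)`` on a common effect allele, the Wald ratio

    r_j = b_yj / b_xj

estimates the causal effect of the exposure on the outcome, identical to
the two-stage least-squares estimate from individual-level data.  Its
standard error comes from the delta method:

    first order   se(r_j) = s_yj / |b_xj|
    second order  se(r_j) = sqrt(s_yj²/b_xj² + b_yj²·s_xj²/b_xj⁴)

Ratios are pooled by a fixed-effect inverse-variance-weighted (IVW)
meta-analysis with weights w_j = 1/se(r_j)²:

    beta = Σ w_j r_j / Σ w_j,    se(beta) = 1 / sqrt(Σ w_j)

which, under first-order weights, is algebraically the slope of a
zero-intercept weighted least-squares regression of outcome betas on
exposure betas with weights 1/s_yj².  Between-instrument heterogeneity
is quantified by Cochran's Q and the I² statistic with a
Higgins–Thompson test-based confidence interval.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

from scipy import stats

from .harmonize import HarmonizedPair

__all__ = [
    "DegenerateInstrumentError",
    "WaldEstimate",
    "HeterogeneityStats",
    "MRResult",
    "wald_ratio",
    "ivw_fixed_effect",
    "cochran_q",
    "z_pvalue",
    "bonferroni",
]

SE_ORDERS = ("first", "second")

#: |beta_exp| below this is treated as a zero (degenerate) instrument.
BETA_EXP_FLOOR = 1e-12

#: instruments with an F-like statistic (beta_exp/se_exp)² below this
#: raise a weak-instrument warning.
WEAK_F_THRESHOLD = 10.0


class DegenerateInstrumentError(ValueError):
    """The SNP-exposure effect is (numerically) zero: ratio undefined."""


@dataclasses.dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal ratio with both delta-method standard errors."""

    snp_id: str
    ratio: float
    se_first: float
    se_second: float
    se_order: str
    weak_instrument: bool = False

    def __post_init__(self) -> None:
        if self.se_order not in SE_ORDERS:
            raise ValueError(f"se_order must be one of {SE_ORDERS}")

    @property
    def se(self) -> float:
        """Standard error under the configured order."""
        return self.se_first if self.se_order == "first" else self.se_second

    @property
    def weight(self) -> float:
        """IVW weight 1/se² under the configured order."""
        return 1.0 / self.se**2


@dataclasses.dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q and I² (in percent) with a 95% confidence interval."""

    q: float
    df: int
    p_q: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float


@dataclasses.dataclass(frozen=True)
class MRResult:
    """Pooled causal estimate for one exposure-outcome pair."""

    exposure: str
    outcome: str
    n_snps: int
    beta: float
    se: float
    z: float
    p: float
    se_order: str
    p_adjusted: float | None = None
    heterogeneity: HeterogeneityStats | None = None
    published_beta: float | None = None
    flags: tuple[str, ...] = ()


def wald_ratio(
    pair: HarmonizedPair,
    se_order: str = "first",
    weak_f_threshold: float = WEAK_F_THRESHOLD,
) -> WaldEstimate:
    """Per-SNP Wald ratio estimate from a harmonized pair.

    Both delta-method SE orders are always computed; ``se_order`` only
    selects which one feeds the IVW weight.  An instrument whose
    exposure association is numerically zero raises
    :class:`DegenerateInstrumentError`; one whose F-like statistic
    (beta_exp/se_exp)² falls below ``weak_f_threshold`` is flagged and
    triggers a warning but is not rejected.
    """
    if pair.dropped:
        raise ValueError(f"{pair.snp_id}: cannot estimate from a dropped pair")
    if se_order not in SE_ORDERS:
        raise ValueError(f"se_order must be one of {SE_ORDERS}")
    bx, sx, by, sy = pair.beta_exp, pair.se_exp, pair.beta_out, pair.se_out
    if abs(bx) < BETA_EXP_FLOOR:
        raise DegenerateInstrumentError(
            f"{pair.snp_id}: exposure beta {bx!r} is numerically zero"
        )
    ratio = by / bx
    se_first = sy / abs(bx)
    se_second = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    weak = (bx / sx) ** 2 < weak_f_threshold
    if weak:
        warnings.warn(
            f"{pair.snp_id}: weak instrument, F-like statistic "
            f"{(bx / sx) ** 2:.2f} < {weak_f_threshold:g}",
            stacklevel=2,
        )
    return WaldEstimate(
        snp_id=pair.snp_id,
        ratio=ratio,
        se_first=se_first,
        se_second=se_second,
        se_order=se_order,
        weak_instrument=weak,
    )


def z_pvalue(beta: float, se: float) -> float:
    """Two-sided p-value of beta/se against a standard normal."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def ivw_fixed_effect(
    estimates: Sequence[WaldEstimate],
    exposure: str = "",
    outcome: str = "",
) -> MRResult:
    """Pool per-SNP Wald ratios with a fixed-effect IVW meta-analysis.

    With a single estimate the pooled beta and SE equal that estimate's
    ratio and SE exactly.  Heterogeneity statistics are attached when at
    least two instruments are pooled.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("cannot pool an empty collection of estimates")
    orders = {e.se_order for e in estimates}
    if len(orders) != 1:
        raise ValueError(f"mixed se_order in pooled estimates: {sorted(orders)}")
    (se_order,) = orders
    weights = [e.weight for e in estimates]
    if not all(math.isfinite(w) and w > 0 for w in weights):
        raise ValueError("all IVW weights must be finite and positive")
    if len(estimates) == 1:
        # single instrument: the pool IS the Wald estimate, bit for bit
        beta, se = estimates[0].ratio, estimates[0].se
    else:
        w_sum = sum(weights)
        beta = sum(w * e.ratio for w, e in zip(weights, estimates)) / w_sum
        se = 1.0 / math.sqrt(w_sum)
    z = beta / se
    p = z_pvalue(beta, se)
    het = _heterogeneity(estimates, beta) if len(estimates) >= 2 else None
    return MRResult(
        exposure=exposure,
        outcome=outcome,
        n_snps=len(estimates),
        beta=beta,
        se=se,
        z=z,
        p=p,
        se_order=se_order,
        heterogeneity=het,
    )


def cochran_q(
    estimates: Sequence[WaldEstimate],
    pooled: "MRResult | float",
) -> HeterogeneityStats | None:
    """Cochran's Q and I² for a set of pooled Wald estimates.

    ``pooled`` may be the :class:`MRResult` or the pooled beta itself.
    Returns ``None`` (not-applicable) for fewer than two estimates.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        return None
    beta = pooled.beta if isinstance(pooled, MRResult) else float(pooled)
    return _heterogeneity(estimates, beta)


def _heterogeneity(estimates: Sequence[WaldEstimate], beta: float) -> HeterogeneityStats:
    k = len(estimates)
    df = k - 1
    q = sum(e.weight * (e.ratio - beta) ** 2 for e in estimates)
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    lo, hi = _i2_ci(q, k)
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i2=i2, i2_ci_low=lo, i2_ci_high=hi)


def _i2_ci(q: float, k: int, level: float = 0.95) -> tuple[float, float]:
    """Higgins–Thompson test-based 95% CI for I², truncated to [0, 100].

    Works on ln H where H = sqrt(Q/(k−1)); the SE of ln H uses the
    test-based formula when Q > k and the asymptotic one otherwise.
    With two studies and Q ≤ k neither formula applies, so the CI is
    maximally uninformative ([0, 100]).
    """
    df = k - 1
    if q > k:
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (
            math.sqrt(2.0 * q) - math.sqrt(2.0 * k - 3.0)
        )
    elif k > 2:
        se_ln_h = math.sqrt(
            (1.0 / (2.0 * (k - 2.0))) * (1.0 - 1.0 / (3.0 * (k - 2.0) ** 2))
        )
    else:
        return 0.0, 100.0
    ln_h = 0.5 * math.log(q / df) if q > 0 else -math.inf
    crit = stats.norm.ppf(0.5 + level / 2.0)
    h_lo = max(1.0, math.exp(ln_h - crit * se_ln_h))
    h_hi = max(1.0, math.exp(ln_h + crit * se_ln_h))

    def h_to_i2(h: float) -> float:
        return max(0.0, min(100.0, 100.0 * (h**2 - 1.0) / h**2))

    return h_to_i2(h_lo), h_to_i2(h_hi)


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjust p-values for a family of ``m`` tests.

    ``m`` defaults to the number of p-values supplied; it may be larger
    (e.g. the full exposure-by-outcome grid) but not smaller, and the
    adjustment min(1, p·m) preserves the ordering of the inputs.
    """
    pvalues = list(pvalues)
    if m is None:
        m = len(pvalues)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(pvalues):
        raise ValueError(f"family size m={m} smaller than number of p-values")
    return [min(1.0, p * m) for p in pvalues]
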