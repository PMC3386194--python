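"""Mutation/deletion-rate estimation from fluctuation assays.

Parallel cultures grown from a small inoculum accumulate mutants according
to the Luria-Delbruck process: a mutation arising early founds a large
clone ("jackpot"), so mutant counts across cultures are highly skewed and
the rate cannot be read off the mean frequency. Two classical estimators
are provided:

* **P0 method** — uses only the fraction of cultures with zero mutants:
  the number of mutations per culture is Poisson, so ``m = -ln(P0)``.
* **Lea-Coulson median method** — solves ``r_median/m - ln(m) = 1.24`` for
  ``m``, where ``r_median`` is the median mutant count per culture.

Both convert ``m`` (expected mutations per culture) to a rate per cell per
generation as ``mu = m / (Nt - N0)``, the number of cell divisions in the
culture; when only a fraction of the culture is plated, the divisor is
scaled by that fraction, since zero counts and medians reflect the plated
sample.

Raw rates are normalized by the deletable window around the marker: the
simple per-kbp rate divides by the largest observed deletion, while the
intrinsic per-kbp^2 rate divides by the product of the estimated deletable
extents on each side, with lower/upper bounds from the 95% upper bound and
the observed maxima respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "DeletableWindow",
    "NormalizedRate",
    "FluctuationError",
    "LEA_COULSON_CONSTANT",
    "estimate_rate_p0",
    "estimate_rate_median",
    "estimate_window",
    "normalize_rate",
    "fold_range",
]

#: Constant of the Lea-Coulson median equation r/m - ln(m) = 1.24.
LEA_COULSON_CONSTANT = 1.24


class FluctuationError(ValueError):
    """An estimator's preconditions are not met by the data."""


@dataclass
class FluctuationExperiment:
    """Mutant counts from parallel cultures plus culture demography.

    ``counts`` are mutant colonies per culture (of the plated fraction);
    ``N0``/``Nt`` the inoculum and final population per culture;
    ``plating_fraction`` the fraction of each culture plated.
    """

    counts: list[int]
    N0: float
    Nt: float
    plating_fraction: float = 1.0
    region: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError("need at least one culture")
        if any(c < 0 for c in self.counts):
            raise ValueError("mutant counts must be non-negative")
        if not self.Nt > self.N0:
            raise ValueError("require Nt > N0")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise ValueError("plating_fraction must be in (0, 1]")

    @property
    def divisions(self) -> float:
        """Cell divisions represented by the plated sample."""
        return (self.Nt - self.N0) * self.plating_fraction

    @property
    def cells_plated(self) -> float:
        return self.Nt * self.plating_fraction

    @property
    def mutant_frequency(self) -> float:
        """Mean mutants per cell plated (the raw per-cell frequency)."""
        return float(np.mean(self.counts)) / self.cells_plated


@dataclass
class RateEstimate:
    """A mutation-rate estimate: m per culture and mu per cell per generation."""

    m: float
    mu: float
    method: str
    se_mu: float
    ci_mu: tuple[float, float]
    mutant_frequency: float | None = None


@dataclass
class DeletableWindow:
    """Deletable extents flanking the marker, estimated from observed maxima.

    ``M1``/``M2`` are the largest observed extents (kbp) left/right of the
    marker over ``k`` independent deletions. Under a uniform-endpoint model
    the point estimate of the true extent is the bias-corrected maximum
    ``L_est = M (k+1)/k`` and the 95% upper bound is ``L_hi = M / 0.05^(1/k)``
    (the L at which observing a maximum <= M has probability 0.05).
    """

    M1: float
    M2: float
    k: int
    L1_est: float = field(init=False)
    L2_est: float = field(init=False)
    L1_hi: float = field(init=False)
    L2_hi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.M1 < 0 or self.M2 < 0:
            raise ValueError("observed extents must be non-negative")
        corr = (self.k + 1) / self.k
        hi = 0.05 ** (-1.0 / self.k)
        self.L1_est = self.M1 * corr
        self.L2_est = self.M2 * corr
        self.L1_hi = self.M1 * hi
        self.L2_hi = self.M2 * hi


@dataclass
class NormalizedRate:
    """Raw, per-kbp, and intrinsic per-kbp^2 deletion rates with bounds."""

    mu_raw: float
    mu_per_kbp: float
    mu_intrinsic_best: float
    mu_intrinsic_lo: float
    mu_intrinsic_hi: float
    region: str = ""


def _clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = beta.ppf(alpha / 2, x, n - x + 1) if x > 0 else 0.0
    hi = beta.ppf(1 - alpha / 2, x + 1, n - x) if x < n else 1.0
    return float(lo), float(hi)


def estimate_rate_p0(exp: FluctuationExperiment) -> RateEstimate:
    """P0-method rate estimate from the fraction of zero-mutant cultures.

    ``m = -ln(P0hat)`` with ``P0hat`` the zero fraction; the SE of mu is
    propagated from the binomial SE of P0hat by the delta method and the CI
    from the Clopper-Pearson interval on P0hat. All cultures zero gives
    ``mu = 0`` with a one-sided upper bound; no culture zero means the
    method is inapplicable (all-jackpot) and raises ``FluctuationError``.
    """
    counts = np.asarray(exp.counts)
    n = len(counts)
    zeros = int(np.sum(counts == 0))
    if zeros == 0:
        raise FluctuationError(
            "all cultures contain mutants (jackpot in every culture): "
            "P0 method inapplicable, use the median method"
        )
    d = exp.divisions
    p0_lo, p0_hi = _clopper_pearson(zeros, n)
    if zeros == n:
        # mu = 0 point estimate with a one-sided upper confidence bound
        return RateEstimate(
            m=0.0,
            mu=0.0,
            method="p0",
            se_mu=0.0,
            ci_mu=(0.0, -math.log(p0_lo) / d),
            mutant_frequency=exp.mutant_frequency,
        )
    p0_hat = zeros / n
    m = -math.log(p0_hat)
    se_p0 = math.sqrt(p0_hat * (1 - p0_hat) / n)
    se_m = se_p0 / p0_hat  # delta method on -ln(p)
    return RateEstimate(
        m=m,
        mu=m / d,
        method="p0",
        se_mu=se_m / d,
        ci_mu=(-math.log(p0_hi) / d, -math.log(p0_lo) / d),
        mutant_frequency=exp.mutant_frequency,
    )


def _lower_middle_median(counts: Sequence[int]) -> int:
    """Median as the lower middle order statistic (an observed count)."""
    s = sorted(counts)
    return s[(len(s) - 1) // 2]


def solve_median_equation(
    r_median: float,
    lc_constant: float = LEA_COULSON_CONSTANT,
    bracket: tuple[float, float] = (1e-6, 1e6),
) -> float:
    """Solve ``r_median/m - ln(m) = lc_constant`` for m by bracketed root-finding."""
    if r_median <= 0:
        raise FluctuationError("median equation requires a positive median count")

    def resid(m: float) -> float:
        return r_median / m - math.log(m) - lc_constant

    lo, hi = bracket
    if resid(lo) <= 0 or resid(hi) >= 0:
        raise FluctuationError(
            f"no root of the median equation in ({lo:g}, {hi:g}) for "
            f"median={r_median}"
        )
    m = brentq(resid, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    assert abs(resid(m)) < 1e-9
    return float(m)


def estimate_rate_median(
    exp: FluctuationExperiment,
    lc_constant: float = LEA_COULSON_CONSTANT,
    n_boot: int = 1000,
    bootstrap_seed: int = 0,
) -> RateEstimate:
    """Lea-Coulson median-method rate estimate.

    Solves ``r_median/m - ln(m) = 1.24`` for m, with the median taken as the
    lower middle order statistic for even-length count lists (the classical
    tables assume an observed, integer count). The SE and 95% CI come from a
    seeded nonparametric bootstrap over cultures; resamples whose median is
    zero (outside the method's domain) are dropped.
    """
    if len(exp.counts) < 2:
        raise FluctuationError("median method needs at least two cultures")
    r_med = _lower_middle_median(exp.counts)
    if r_med == 0:
        raise FluctuationError(
            "median mutant count is zero: outside the median method's domain, "
            "use the P0 method"
        )
    d = exp.divisions
    m = solve_median_equation(r_med, lc_constant)
    mu = m / d

    rng = np.random.default_rng(bootstrap_seed)
    counts = np.asarray(exp.counts)
    boot_mu = []
    for _ in range(n_boot):
        res = counts[rng.integers(0, len(counts), size=len(counts))]
        bm = _lower_middle_median(res)
        if bm > 0:
            boot_mu.append(solve_median_equation(bm, lc_constant) / d)
    if len(boot_mu) >= 10:
        se = float(np.std(boot_mu, ddof=1))
        ci = tuple(float(q) for q in np.quantile(boot_mu, [0.025, 0.975]))
    else:  # pragma: no cover - degenerate bootstrap
        se, ci = float("nan"), (float("nan"), float("nan"))
    return RateEstimate(
        m=m,
        mu=mu,
        method="median",
        se_mu=se,
        ci_mu=ci,
        mutant_frequency=exp.mutant_frequency,
    )


def estimate_window(
    extents_left_kbp: Sequence[float], extents_right_kbp: Sequence[float]
) -> DeletableWindow:
    """Estimate the deletable window from per-deletion extents (kbp).

    Each of the k independent deletions contributes its extent left and
    right of the marker; the two lists must therefore have equal length.
    """
    if len(extents_left_kbp) == 0 or len(extents_right_kbp) == 0:
        raise ValueError("need at least one observed deletion per side")
    if len(extents_left_kbp) != len(extents_right_kbp):
        raise ValueError(
            "left and right extents must come from the same deletions "
            f"(got {len(extents_left_kbp)} vs {len(extents_right_kbp)})"
        )
    if min(extents_left_kbp) < 0 or min(extents_right_kbp) < 0:
        raise ValueError("extents must be non-negative")
    return DeletableWindow(
        M1=float(max(extents_left_kbp)),
        M2=float(max(extents_right_kbp)),
        k=len(extents_left_kbp),
    )


def normalize_rate(
    rate: RateEstimate,
    window: DeletableWindow,
    largest_deletion_kbp: float,
    region: str = "",
) -> NormalizedRate:
    """Normalize a raw rate by the deletable window.

    ``mu_per_kbp`` divides by the largest observed deletion; the intrinsic
    per-kbp^2 rate divides by the product of the two side extents — best
    estimate from L_est, lower bound from the 95% upper window bounds, upper
    bound from the observed maxima (the minimum possible window).
    """
    if largest_deletion_kbp <= 0:
        raise ValueError("largest_deletion_kbp must be > 0")
    for v, name in [
        (window.L1_est * window.L2_est, "L_est"),
        (window.L1_hi * window.L2_hi, "L_hi"),
        (window.M1 * window.M2, "M"),
    ]:
        if v <= 0:
            raise ValueError(f"zero deletable-window dimension ({name})")
    return NormalizedRate(
        mu_raw=rate.mu,
        mu_per_kbp=rate.mu / largest_deletion_kbp,
        mu_intrinsic_best=rate.mu / (window.L1_est * window.L2_est),
        mu_intrinsic_lo=rate.mu / (window.L1_hi * window.L2_hi),
        mu_intrinsic_hi=rate.mu / (window.M1 * window.M2),
        region=region,
    )


def fold_range(rates: Sequence[NormalizedRate], attr: str = "mu_per_kbp") -> float:
    """Max/min ratio of the chosen rate field across regions."""
    if len(rates) == 0:
        raise ValueError("need at least one rate")
    values = [getattr(r, attr) for r in rates]
    if min(values) <= 0:
        raise ValueError("fold range undefined with non-positive rates")
    return max(values) / min(values)
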