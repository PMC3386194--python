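"""Fitness estimation: growth rates, competition selection coefficients, burden.

Three complementary fitness readouts for deletion mutants:

* exponential growth rate, as the maximal slope of ln(OD600) over a sliding
  window of readings above the detection floor;
* selection coefficient per generation, as the least-squares slope of the
  log count ratio of two fluorescently labelled competitors against
  cumulative generations of co-culture;
* the protein-burden prediction: expressing a non-used protein of length L
  amino acids at n copies per cell costs s = nL/r0 in fitness, with
  r0 = 1e9 the total amino acids polymerized into protein per cell per
  doubling, so deleting a set of unneeded genes is predicted to gain
  sum(n_i L_i)/r0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "CompetitionTrajectory",
    "SelectionEstimate",
    "GeneBurdenTable",
    "DEFAULT_R0",
    "FLAGELLAR_ENERGY_COST",
    "fit_growth_rate",
    "relative_growth_rate",
    "fit_selection_coefficient",
    "burden_selection",
]

logger = logging.getLogger(__name__)

#: Total amino acids incorporated into protein per bacterial cell (r0).
DEFAULT_R0 = 1e9

#: Estimated fraction of a cell's total energy budget dissipated running the
#: flagella (documented literature-derived constant; its derivation is not
#: reimplemented here). Useful as a comparison point for the fitness gain of
#: motility-gene deletions.
FLAGELLAR_ENERGY_COST = 0.045


@dataclass
class GrowthCurve:
    """An OD600 time series for one culture."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass
class GrowthRateEstimate:
    rate: float  # per hour
    window: tuple[float, float]
    r2: float
    replicate_id: str = ""
    relative_rate: float | None = None


@dataclass
class CompetitionTrajectory:
    """Two-channel count time series against cumulative generations."""

    generations: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.counts_a = np.asarray(self.counts_a, dtype=float)
        self.counts_b = np.asarray(self.counts_b, dtype=float)
        if not (
            self.generations.shape == self.counts_a.shape == self.counts_b.shape
        ):
            raise ValueError("all three series must have equal length")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")
        if np.any(self.counts_a < 0) or np.any(self.counts_b < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class SelectionEstimate:
    s: float  # per generation
    se_s: float
    n_points: int
    log_base: str = "e"


def fit_growth_rate(
    curve: GrowthCurve,
    window_points: int = 5,
    detection_floor: float = 0.01,
) -> GrowthRateEstimate:
    """Exponential growth rate as the max slope of ln(OD) over a sliding window.

    Only contiguous runs of ``window_points`` readings strictly above the
    detection floor are considered; among all such windows the one with the
    largest ln-OD slope wins (earliest window on ties). The fit r^2 is
    reported for the chosen window.
    """
    if window_points < 2:
        raise ValueError("window_points must be >= 2")
    mask = curve.od > detection_floor
    n = len(curve.times)
    best = None
    for i in range(n - window_points + 1):
        if not mask[i : i + window_points].all():
            continue
        t = curve.times[i : i + window_points]
        y = np.log(curve.od[i : i + window_points])
        fit = linregress(t, y)
        if best is None or fit.slope > best[0].slope:
            best = (fit, i)
    if best is None:
        raise ValueError(
            f"fewer than {window_points} consecutive readings above the "
            f"detection floor {detection_floor}"
        )
    fit, i = best
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return GrowthRateEstimate(
        rate=float(fit.slope),
        window=(float(curve.times[i]), float(curve.times[i + window_points - 1])),
        r2=r2,
        replicate_id=curve.replicate_id,
    )


def relative_growth_rate(
    mutant: GrowthRateEstimate, reference: GrowthRateEstimate
) -> float:
    """Mutant growth rate relative to the reference (reference = 1.0)."""
    if reference.rate == 0:
        raise ValueError("reference growth rate is zero")
    return mutant.rate / reference.rate


def fit_selection_coefficient(
    traj: CompetitionTrajectory, log_base: str = "e"
) -> SelectionEstimate:
    """Selection coefficient as the OLS slope of the log count ratio.

    s is the slope of log(counts_a / counts_b) against generations; with
    natural logs (default) a noiseless per-generation advantage (1+s) gives
    exactly ln(1+s). Timepoints where either channel is zero are dropped
    with a logged warning (near fixation the linear model fails anyway).
    ``log_base`` may be "e" or "2".
    """
    if log_base not in ("e", "2"):
        raise ValueError("log_base must be 'e' or '2'")
    usable = (traj.counts_a > 0) & (traj.counts_b > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "dropping %d timepoint(s) with a zero count at generations %s",
            n_dropped,
            traj.generations[~usable].tolist(),
        )
    if int(usable.sum()) < 3:
        raise ValueError(
            f"only {int(usable.sum())} usable timepoints; need at least 3 "
            "for a slope"
        )
    x = traj.generations[usable]
    ratio = traj.counts_a[usable] / traj.counts_b[usable]
    y = np.log(ratio) if log_base == "e" else np.log2(ratio)
    fit = linregress(x, y)
    return SelectionEstimate(
        s=float(fit.slope),
        se_s=float(fit.stderr),
        n_points=int(usable.sum()),
        log_base=log_base,
    )


@dataclass
class GeneBurdenTable:
    """Per-gene protein length (aa) and copy number per cell."""

    table: pd.DataFrame  # columns: gene, length_aa, copies

    REQUIRED = ("gene", "length_aa", "copies")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene table missing column(s): {', '.join(missing)}")
        if len(self.table) and (self.table["length_aa"] < 1).any():
            raise ValueError("protein lengths must be >= 1 aa")
        if len(self.table) and (self.table["copies"] < 0).any():
            raise ValueError("copy numbers must be >= 0")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float]]
    ) -> "GeneBurdenTable":
        return cls(
            pd.DataFrame(list(records), columns=["gene", "length_aa", "copies"])
        )


def burden_selection(
    genes: GeneBurdenTable | pd.DataFrame, r0: float = DEFAULT_R0
) -> float:
    """Predicted fitness gain of deleting the listed non-used genes.

    Each gene expressing n protein copies of length L amino acids costs
    nL/r0 in fitness; the predicted benefit of deleting the whole set is the
    sum ``sum(n_i * L_i) / r0`` (linear in n, L and 1/r0, additive over
    disjoint gene sets). An empty table predicts 0.
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    if isinstance(genes, pd.DataFrame):
        genes = GeneBurdenTable(genes)
    if len(genes.table) == 0:
        return 0.0
    return float((genes.table["copies"] * genes.table["length_aa"]).sum() / r0)


def pooled_selection_estimate(
    estimates: list[SelectionEstimate],
) -> SelectionEstimate:
    """Inverse-variance pooled s across replicate competitions."""
    if not estimates:
        raise ValueError("no estimates to pool")
    if len({e.log_base for e in estimates}) != 1:
        raise ValueError("cannot pool estimates with mixed log bases")
    w = np.array([1.0 / e.se_s**2 if e.se_s > 0 else np.inf for e in estimates])
    s = np.array([e.s for e in estimates])
    if np.any(np.isinf(w)):  # an exact replicate dominates
        exact = s[np.isinf(w)]
        return SelectionEstimate(
            s=float(np.mean(exact)),
            se_s=0.0,
            n_points=sum(e.n_points for e in estimates),
            log_base=estimates[0].log_base,
        )
    return SelectionEstimate(
        s=float(np.sum(w * s) / np.sum(w)),
        se_s=float(math.sqrt(1.0 / np.sum(w))),
        n_points=sum(e.n_points for e in estimates),
        log_base=estimates[0].log_base,
    )
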