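"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of its :class:`~deletometer.config.SimulationConfig`
(and an optional seed override): identical inputs give identical outputs.
The statistical structure matches what the downstream estimators assume —
Luria-Delbruck mutant counts for the fluctuation module, conditioned-uniform
deletion endpoints with planted junction direct repeats for the junctions
module, binomially sampled two-color counts for the competition fitter, and
logistic OD600 curves with additive noise for the growth-rate fitter.
"""

from __future__ import annotations

import math

import numpy as np

from .config import SimulationConfig
from .fitness import CompetitionTrajectory, GrowthCurve
from .fluctuation import FluctuationExperiment
from .junctions import DeletionEvent

__all__ = [
    "simulate_fluctuation_cultures",
    "simulate_deletion_events",
    "random_genome",
    "plant_junction",
    "simulate_competition",
    "simulate_growth_curve",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(cfg: SimulationConfig, seed: int | None, stream: int) -> np.random.Generator:
    """Per-generator random stream fanned out from the root seed."""
    root = cfg.seed if seed is None else seed
    return np.random.default_rng([stream, root])


def simulate_fluctuation_cultures(
    cfg: SimulationConfig, seed: int | None = None
) -> FluctuationExperiment:
    """Draw one Luria-Delbruck mutant count per parallel culture.

    Each culture doubles from N0 to Nt over g = log2(Nt/N0) generations
    (the last doubling may be a fractional interval, with proportionally
    fewer births). In each doubling, new mutants arise as a Poisson draw
    with mean mu_true x (cells born in that doubling); each mutant founds a
    lineage that doubles deterministically, at the wild-type rate, for the
    remaining generations. The reported count is the final number of mutant
    cells, binomially thinned by the plating fraction. Because total births
    sum to Nt - N0, the zero-count probability is exp(-mu_true (Nt - N0)),
    the identity the P0 estimator inverts.
    """
    rng = _rng(cfg, seed, stream=1)
    g_total = math.log2(cfg.Nt / cfg.N0)
    counts: list[int] = []
    for _ in range(cfg.n_cultures):
        mutants = 0.0
        n = cfg.N0
        g = 0.0
        while g < g_total - 1e-12:
            step = min(1.0, g_total - g)
            n_next = n * 2.0**step
            births = n_next - n
            k = rng.poisson(cfg.mu_true * births) if cfg.mu_true > 0 else 0
            if k:
                # remaining doublings after this interval completes
                mutants += k * 2.0 ** (g_total - g - step)
            n = n_next
            g += step
        total = int(round(mutants))
        if cfg.plating_fraction < 1.0 and total > 0:
            total = int(rng.binomial(total, cfg.plating_fraction))
        counts.append(total)
    return FluctuationExperiment(
        counts=counts,
        N0=cfg.N0,
        Nt=cfg.Nt,
        plating_fraction=cfg.plating_fraction,
    )


def simulate_deletion_events(
    cfg: SimulationConfig,
    marker_position: int,
    n_events: int = 30,
    chrom: str = "chr",
    seed: int | None = None,
) -> list[DeletionEvent]:
    """Draw deletion endpoints uniformly over the deletable window.

    Left endpoints are uniform on [marker - deletable_left, marker], right
    endpoints uniform on [marker, marker + deletable_right]; draws are
    rejected until the deletion spans the marker and removes at least
    min_deletion_kbp. Coordinates are 0-based half-open and clipped to the
    genome.
    """
    if not (0 <= marker_position < cfg.genome_length_bp):
        raise ValueError("marker_position must lie inside the genome")
    left_bp = int(round(cfg.deletable_left_kbp * 1000))
    right_bp = int(round(cfg.deletable_right_kbp * 1000))
    min_bp = int(round(cfg.min_deletion_kbp * 1000))
    if left_bp + right_bp < min_bp:
        raise ValueError(
            "deletable window smaller than the minimum detectable deletion: "
            f"{left_bp + right_bp} bp available < {min_bp} bp required"
        )
    lo = max(0, marker_position - left_bp)
    hi = min(cfg.genome_length_bp, marker_position + right_bp)
    if hi - lo < min_bp:
        raise ValueError(
            "deletable window truncated by the genome ends falls below the "
            f"minimum deletion size ({hi - lo} bp < {min_bp} bp)"
        )
    rng = _rng(cfg, seed, stream=2)
    if min_bp == hi - lo:
        # the constraint admits exactly one endpoint pair: the full window
        return [
            DeletionEvent(chrom=chrom, start=lo, end=hi, name=f"del{i + 1}")
            for i in range(n_events)
        ]
    starts: list[int] = []
    ends: list[int] = []
    while len(starts) < n_events:
        batch = max(64, 2 * (n_events - len(starts)))
        s = rng.integers(lo, marker_position + 1, size=batch)
        e = rng.integers(marker_position, hi + 1, size=batch)
        ok = (e - s >= max(min_bp, 1)) & (s <= marker_position) & (e > marker_position)
        starts.extend(int(v) for v in s[ok])
        ends.extend(int(v) for v in e[ok])
    return [
        DeletionEvent(chrom=chrom, start=starts[i], end=ends[i], name=f"del{i + 1}")
        for i in range(n_events)
    ]


def random_genome(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T sequence."""
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def plant_junction(
    genome: str,
    event: DeletionEvent,
    homology_bp: int,
    seed: int = 0,
) -> str:
    """Plant an exact direct repeat of ``homology_bp`` at a deletion's endpoints.

    Returns a copy of the genome in which the ``homology_bp`` bases starting
    at the left endpoint equal those starting at the right endpoint, and in
    which no longer accidental repeat exists at the junction: the bases
    immediately after each copy are forced to differ (re-randomized on
    collision), as are the bases immediately upstream of the two endpoints,
    so downstream recovery returns exactly ``homology_bp`` regardless of
    scan direction.
    """
    if homology_bp < 0:
        raise ValueError("homology_bp must be >= 0")
    if event.end > len(genome):
        raise ValueError("event extends beyond the genome")
    if homology_bp > event.size or event.end + homology_bp > len(genome):
        raise ValueError(
            f"homology of {homology_bp} bp does not fit the flanks "
            f"(deletion size {event.size} bp, downstream flank "
            f"{len(genome) - event.end} bp)"
        )
    rng = np.random.default_rng([3, seed])
    seq = list(genome)
    start, end, h = event.start, event.end, homology_bp
    seq[end : end + h] = seq[start : start + h]

    def _break_match(i: int, j: int) -> None:
        """Re-randomize position j until it differs from position i."""
        if i >= len(seq) or j >= len(seq) or i < 0 or j < 0 or i == j:
            return
        while seq[j].upper() == seq[i].upper():
            seq[j] = str(rng.choice(_BASES).decode("ascii"))

    _break_match(start + h, end + h)  # no accidental forward extension
    _break_match(end - 1, start - 1)  # no accidental upstream repeat
    return "".join(seq)


def simulate_competition(
    cfg: SimulationConfig,
    initial_ratio: float = 1.0,
    exact_counts: bool = False,
    seed: int | None = None,
) -> CompetitionTrajectory:
    """Two-color competition counts under a constant per-generation advantage.

    The true mutant frequency evolves deterministically with advantage
    s_true per generation across n_cycles daily cycles of
    generations_per_cycle generations; at each daily timepoint (including
    generation 0) the observed channel-A count is a binomial draw of
    events_per_timepoint cells at the true frequency. With
    ``exact_counts=True`` the expected (real-valued) counts are returned
    instead — the infinite-events limit.
    """
    if initial_ratio <= 0:
        raise ValueError("initial_ratio must be > 0")
    rng = _rng(cfg, seed, stream=4)
    p0 = initial_ratio / (1.0 + initial_ratio)
    gens = np.arange(cfg.n_cycles + 1) * cfg.generations_per_cycle
    odds = (p0 / (1.0 - p0)) * (1.0 + cfg.s_true) ** gens
    p = odds / (1.0 + odds)
    n = cfg.events_per_timepoint
    if exact_counts:
        counts_a = n * p
        counts_b = n * (1.0 - p)
    else:
        counts_a = rng.binomial(n, p).astype(float)
        counts_b = n - counts_a
    return CompetitionTrajectory(
        generations=gens, counts_a=counts_a, counts_b=counts_b
    )


def simulate_growth_curve(
    cfg: SimulationConfig, replicate_id: str = "r1", seed: int | None = None
) -> GrowthCurve:
    """Logistic OD600 trajectory with additive Gaussian noise.

    OD(t) = K x0 e^{rt} / (K + x0 (e^{rt} - 1)) sampled every
    sample_interval_h over duration_h, plus N(0, noise_sd) noise, floored
    at the detection limit.
    """
    rng = _rng(cfg, seed, stream=5)
    t = np.arange(0.0, cfg.duration_h + 1e-9, cfg.sample_interval_h)
    r, K, x0 = cfg.growth_rate_true, cfg.carrying_capacity, cfg.od_initial
    ert = np.exp(r * t)
    od = K * x0 * ert / (K + x0 * (ert - 1.0))
    if cfg.noise_sd > 0:
        od = od + rng.normal(0.0, cfg.noise_sd, size=od.shape)
    od = np.maximum(od, cfg.detection_floor)
    return GrowthCurve(times=t, od=od, replicate_id=replicate_id)
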