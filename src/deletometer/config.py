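"""Shared simulation configuration.

A single :class:`SimulationConfig` carries every parameter the synthetic-data
generators need, with defaults matching the assay conditions the package
models: nine parallel 1 ml overnight cultures inoculated with 10^6 cells and
grown to ~10^9, deletions of at least 2 kbp around a chromosomal marker,
daily 1:1000 serial passage (log2(1000) ~ 9.97 generations per cycle), and
~10^5 counted cells per competition timepoint.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

__all__ = ["SimulationConfig", "GENERATIONS_PER_1000X_DILUTION"]

#: Generations of regrowth after a 1:1000 dilution (log2 of the dilution factor).
GENERATIONS_PER_1000X_DILUTION: float = math.log2(1000.0)

# Default planted-homology lengths for a batch of 30 simulated deletion
# junctions: 19 with short direct repeats of 6-15 bp and 11 with 0-4 bp,
# mirroring the empirical split between microhomology-mediated and
# low/no-homology junctions in sequenced spontaneous deletions.
_DEFAULT_HOMOLOGIES: tuple[int, ...] = (
    6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 6, 7, 8, 9, 10, 11, 12, 13, 14,
    0, 0, 1, 2, 3, 4, 0, 1, 2, 3, 4,
)


@dataclass
class SimulationConfig:
    """Parameters for every synthetic-data generator.

    Parameters
    ----------
    seed
        Root seed; all generator randomness derives from it.
    n_cultures
        Parallel cultures per fluctuation assay.
    N0, Nt
        Cells inoculated into, and present at plating in, each culture.
    mu_true
        Deletion rate per cell per generation used to generate mutant counts.
    plating_fraction
        Fraction of each culture actually plated (900 ul of 1 ml by default);
        observed mutant counts are binomially thinned by this factor.
    deletable_left_kbp, deletable_right_kbp
        Extent of non-essential (deletable) DNA flanking the marker, in kbp.
    min_deletion_kbp
        Detection threshold: a deletion must remove at least this much DNA
        (it must take out all three cassette markers) to be scored.
    genome_length_bp
        Length of simulated reference sequences.
    homology_lengths
        Direct-repeat lengths (bp) planted at simulated deletion junctions.
    s_true
        Per-generation selection coefficient of the labelled competitor.
    generations_per_cycle
        Generations of regrowth per serial-passage cycle.
    n_cycles
        Daily passage cycles per simulated competition.
    events_per_timepoint
        Cells counted per competition timepoint (two-color flow counts).
    growth_rate_true, carrying_capacity, od_initial
        Logistic growth-curve parameters (per hour, OD600, OD600).
    noise_sd
        Additive Gaussian noise on OD600 readings.
    duration_h, sample_interval_h
        Growth-curve sampling span and interval.
    detection_floor
        Plate-reader detection limit; readings below it are clamped up to it.
    """

    seed: int = 0

    # fluctuation-assay demography
    n_cultures: int = 9
    N0: float = 1e6
    Nt: float = 1e9
    mu_true: float = 1e-8
    plating_fraction: float = 0.9

    # deletion geometry
    deletable_left_kbp: float = 10.0
    deletable_right_kbp: float = 10.0
    min_deletion_kbp: float = 2.0
    genome_length_bp: int = 100_000
    homology_lengths: list[int] = field(
        default_factory=lambda: list(_DEFAULT_HOMOLOGIES)
    )

    # two-color competition
    s_true: float = 0.05
    generations_per_cycle: float = GENERATIONS_PER_1000X_DILUTION
    n_cycles: int = 5
    events_per_timepoint: int = 100_000

    # growth curves
    growth_rate_true: float = 1.2
    carrying_capacity: float = 1.5
    od_initial: float = 0.01
    noise_sd: float = 0.005
    duration_h: float = 16.0
    sample_interval_h: float = 0.25
    detection_floor: float = 0.01

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cultures < 1:
            raise ValueError("n_cultures must be >= 1")
        if not (self.Nt > self.N0 >= 1):
            raise ValueError("require Nt > N0 >= 1")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise ValueError("plating_fraction must be in (0, 1]")
        nonneg = {
            "mu_true": self.mu_true,
            "deletable_left_kbp": self.deletable_left_kbp,
            "deletable_right_kbp": self.deletable_right_kbp,
            "min_deletion_kbp": self.min_deletion_kbp,
            "events_per_timepoint": self.events_per_timepoint,
            "growth_rate_true": self.growth_rate_true,
            "carrying_capacity": self.carrying_capacity,
            "noise_sd": self.noise_sd,
            "od_initial": self.od_initial,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.genome_length_bp < 1:
            raise ValueError("genome_length_bp must be >= 1")
        if any(h < 0 for h in self.homology_lengths):
            raise ValueError("homology_lengths must be >= 0")
        if self.min_deletion_kbp > self.deletable_left_kbp + self.deletable_right_kbp:
            raise ValueError(
                "min_deletion_kbp exceeds the total deletable window "
                f"({self.min_deletion_kbp} > {self.deletable_left_kbp} + "
                f"{self.deletable_right_kbp} kbp): no deletion can ever be detected"
            )
        if self.generations_per_cycle <= 0:
            raise ValueError("generations_per_cycle must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sample_interval_h <= 0 or self.duration_h <= 0:
            raise ValueError("sampling span and interval must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown SimulationConfig key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**d)
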