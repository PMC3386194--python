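"""Deletion-junction microhomology analysis.

A spontaneous deletion formed between two copies of a short direct repeat
retains a single copy of the repeat at the junction. Given the reference
sequence and the deletion endpoints, the length of the maximal exact direct
repeat flanking the junction is diagnostic of mechanism: RecA-mediated
homologous recombination needs roughly 25 bp or more of identity, so
junctions with only short (~5-24 bp) repeats point to RecA-independent
recombination, and junctions with <=4 bp to end-joining-like or
no-homology events.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DeletionEvent",
    "JunctionReport",
    "MECHANISM_CLASSES",
    "RECA_MIN_HOMOLOGY_BP",
    "MICROHOMOLOGY_MIN_BP",
    "find_junction_homology",
    "classify_junction",
    "summarize_junctions",
]

#: Minimum identity (bp) for RecA-mediated strand exchange.
RECA_MIN_HOMOLOGY_BP = 25
#: Smallest repeat scored as microhomology (4 bp and below is "none or low").
MICROHOMOLOGY_MIN_BP = 5

MECHANISM_CLASSES = ("none_or_low", "microhomology", "reca_capable")

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class DeletionEvent:
    """A deletion on a reference sequence, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"deletion end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionReport:
    """Homology found at one deletion junction and its mechanism call."""

    event: DeletionEvent
    homology_bp: int
    mechanism_class: str
    left_flank: str = ""
    right_flank: str = ""


def _match_forward(genome: str, i: int, j: int, max_scan: int, circular: bool) -> int:
    """Length of the exact A/C/G/T match of genome[i:] vs genome[j:]."""
    n = len(genome)
    h = 0
    while h < max_scan:
        ii, jj = i + h, j + h
        if circular:
            ii %= n
            jj %= n
        elif ii >= n or jj >= n:
            break
        a, b = genome[ii].upper(), genome[jj].upper()
        if a not in _ACGT or b not in _ACGT or a != b:
            break
        h += 1
    return h


def _match_backward(genome: str, i: int, j: int, max_scan: int, circular: bool) -> int:
    n = len(genome)
    h = 0
    while h < max_scan:
        ii, jj = i - 1 - h, j - 1 - h
        if circular:
            ii %= n
            jj %= n
        elif ii < 0 or jj < 0:
            break
        a, b = genome[ii].upper(), genome[jj].upper()
        if a not in _ACGT or b not in _ACGT or a != b:
            break
        h += 1
    return h


def find_junction_homology(
    genome: str,
    event: DeletionEvent,
    max_scan: int = 50,
    *,
    scan_upstream: bool = False,
    circular: bool = False,
) -> JunctionReport:
    """Measure the maximal exact direct repeat at a deletion junction.

    The repeat convention is downstream: ``homology_bp`` is the largest
    ``h <= max_scan`` with ``genome[start:start+h] == genome[end:end+h]``
    case-insensitively over A/C/G/T (any other base terminates the match).
    Under this convention the null tail on uniform random sequence is
    ``P(h >= x) = 0.25**x``. With ``scan_upstream=True`` the mirrored
    upstream scan is also computed and the maximum of the two reported
    (which roughly doubles the null tail).

    Scans truncate at the sequence ends unless ``circular`` is set, in which
    case they wrap.
    """
    if max_scan < 1:
        raise ValueError("max_scan must be >= 1")
    if event.end > len(genome):
        raise ValueError(
            f"deletion [{event.start}, {event.end}) extends beyond the "
            f"{len(genome)} bp sequence {event.chrom!r}"
        )
    h = _match_forward(genome, event.start, event.end, max_scan, circular)
    if scan_upstream:
        h = max(h, _match_backward(genome, event.start, event.end, max_scan, circular))
    return JunctionReport(
        event=event,
        homology_bp=h,
        mechanism_class=classify_junction(h),
        left_flank=genome[event.start : event.start + max_scan],
        right_flank=genome[event.end : event.end + max_scan],
    )


def classify_junction(homology_bp: int) -> str:
    """Mechanism class implied by junction homology length.

    >=25 bp supports RecA-mediated recombination; 5-24 bp is scored as
    microhomology (RecA-independent); 0-4 bp as none_or_low.
    """
    if homology_bp < 0:
        raise ValueError("homology length cannot be negative")
    if homology_bp >= RECA_MIN_HOMOLOGY_BP:
        return "reca_capable"
    if homology_bp >= MICROHOMOLOGY_MIN_BP:
        return "microhomology"
    return "none_or_low"


def summarize_junctions(reports: list[JunctionReport]) -> pd.DataFrame:
    """Count and fraction of junctions per mechanism class.

    Returns one row per class (all three classes always present) with
    columns ``mechanism_class``, ``n`` and ``fraction``; fractions are 0
    for an empty input rather than raising.
    """
    n_total = len(reports)
    counts = {c: 0 for c in MECHANISM_CLASSES}
    for r in reports:
        counts[r.mechanism_class] += 1
    return pd.DataFrame(
        {
            "mechanism_class": list(MECHANISM_CLASSES),
            "n": [counts[c] for c in MECHANISM_CLASSES],
            "fraction": [
                counts[c] / n_total if n_total else 0.0 for c in MECHANISM_CLASSES
            ],
            "n_total": n_total,
        }
    )


def junction_report_table(reports: list[JunctionReport]) -> pd.DataFrame:
    """Per-junction long table (chrom, start, end, size, homology_bp, class)."""
    return pd.DataFrame(
        {
            "chrom": [r.event.chrom for r in reports],
            "start": [r.event.start for r in reports],
            "end": [r.event.end for r in reports],
            "size": [r.event.size for r in reports],
            "homology_bp": [r.homology_bp for r in reports],
            "mechanism_class": [r.mechanism_class for r in reports],
        }
    )
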