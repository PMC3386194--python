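"""Readers and writers for the package's interchange formats.

Tabular data travels as TSV with a header row; genomic data as FASTA
(via Biopython) and BED3+ (0-based half-open). Readers validate and reject
malformed input with the offending line named rather than coercing; every
writer produces files its paired reader round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fitness import CompetitionTrajectory, GeneBurdenTable, GrowthCurve
from .fluctuation import FluctuationExperiment
from .junctions import DeletionEvent

__all__ = [
    "read_deletions",
    "write_deletions",
    "read_genome",
    "write_genome",
    "read_fluctuation",
    "write_fluctuation",
    "read_competition",
    "write_competition",
    "read_growth_curves",
    "write_growth_curves",
    "read_gene_table",
    "write_gene_table",
    "write_provenance",
]


class FormatError(ValueError):
    """Malformed input file."""


# --- BED ---------------------------------------------------------------


def read_deletions(path: str | Path) -> list[DeletionEvent]:
    """Parse BED3+ deletion records; '#', 'track' and 'browser' lines skipped."""
    events: list[DeletionEvent] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated "
                    f"BED fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from None
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end must exceed start ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else "."
            events.append(DeletionEvent(chrom=chrom, start=start, end=end, name=name))
    return events


def write_deletions(events: list[DeletionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.name}\n")


# --- FASTA -------------------------------------------------------------


def read_genome(path: str | Path) -> dict[str, str]:
    """FASTA to {name: sequence}; names taken up to first whitespace."""
    genomes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genomes:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        genomes[rec.id] = str(rec.seq)
    return genomes


def write_genome(genomes: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --- fluctuation counts ------------------------------------------------


def write_fluctuation(exp: FluctuationExperiment, path: str | Path) -> None:
    """TSV of per-culture counts with demography in '#key=value' header lines."""
    with open(path, "w") as fh:
        fh.write(f"#N0={exp.N0!r}\n#Nt={exp.Nt!r}\n")
        fh.write(f"#plating_fraction={exp.plating_fraction!r}\n")
        if exp.region:
            fh.write(f"#region={exp.region}\n")
        fh.write("culture_id\tmutant_count\tcells_plated\n")
        for i, c in enumerate(exp.counts, start=1):
            fh.write(f"c{i}\t{c}\t{exp.cells_plated!r}\n")


def read_fluctuation(path: str | Path) -> FluctuationExperiment:
    meta: dict[str, str] = {}
    rows: list[int] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            if not line.strip():
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["culture_id", "mutant_count"]:
                    raise FormatError(f"{path}:{lineno}: unexpected header {line!r}")
                header_seen = True
                continue
            fields = line.split("\t")
            try:
                rows.append(int(fields[1]))
            except (IndexError, ValueError):
                raise FormatError(
                    f"{path}:{lineno}: malformed count row {line!r}"
                ) from None
    for key in ("N0", "Nt", "plating_fraction"):
        if key not in meta:
            raise FormatError(f"{path}: missing '#{key}=' metadata line")
    return FluctuationExperiment(
        counts=rows,
        N0=float(meta["N0"]),
        Nt=float(meta["Nt"]),
        plating_fraction=float(meta["plating_fraction"]),
        region=meta.get("region", ""),
    )


# --- competition & growth TSV ------------------------------------------


def write_competition(traj: CompetitionTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "generations": traj.generations,
            "count_a": traj.counts_a,
            "count_b": traj.counts_b,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_competition(path: str | Path) -> CompetitionTrajectory:
    df = _read_tsv(path, {"generations", "count_a", "count_b"})
    return CompetitionTrajectory(
        generations=df["generations"].to_numpy(),
        counts_a=df["count_a"].to_numpy(),
        counts_b=df["count_b"].to_numpy(),
    )


def write_growth_curves(curves: list[GrowthCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"time_h": c.times, "od": c.od, "replicate": c.replicate_id}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    df = _read_tsv(path, {"time_h", "od", "replicate"})
    return [
        GrowthCurve(
            times=sub["time_h"].to_numpy(),
            od=sub["od"].to_numpy(),
            replicate_id=str(rep),
        )
        for rep, sub in df.groupby("replicate", sort=False)
    ]


def write_gene_table(genes: GeneBurdenTable, path: str | Path) -> None:
    genes.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_table(path: str | Path) -> GeneBurdenTable:
    df = _read_tsv(path, set(GeneBurdenTable.REQUIRED))
    return GeneBurdenTable(df)


def _read_tsv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from None
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    return df


# --- provenance --------------------------------------------------------


def write_provenance(path: str | Path, config: dict, seed: int) -> None:
    """Record the exact config, package version and seed next to the outputs."""
    from . import __version__

    with open(path, "w") as fh:
        json.dump(
            {"package": "deletometer", "version": __version__, "seed": seed,
             "config": config},
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
        fh.write("\n")
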