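"""End-to-end demo pipeline: simulate -> estimate -> report.

A declarative YAML config drives one full pass through the package: for
each configured chromosomal region it simulates a fluctuation assay,
estimates and normalizes the deletion rate, simulates deletions with
planted junction repeats and classifies them, fits competition and
growth-curve fitness, evaluates the protein-burden prediction, and
computes deterministic take-over times. All randomness fans out from the
single root seed, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixation as fx
from . import fluctuation as fl
from . import io as dio
from . import junctions as jn
from . import synthetic as syn
from .config import SimulationConfig
from .fitness import (
    GeneBurdenTable,
    burden_selection,
    fit_growth_rate,
    fit_selection_coefficient,
    relative_growth_rate,
)

__all__ = ["RunConfig", "load_config", "load_demo_config", "run_pipeline",
           "PipelineError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir", "verbosity", "regions", "fluctuation", "junctions",
         "competition", "growth", "burden", "fixation"},
    "regions[]": {"name", "mu_true", "deletable_left_kbp", "deletable_right_kbp"},
    "fluctuation": {"n_cultures", "N0", "Nt", "plating_fraction",
                    "min_deletion_kbp"},
    "junctions": {"n_events", "genome_length_bp", "max_scan"},
    "competition": {"s_true", "n_cycles", "events_per_timepoint",
                    "generations_per_cycle"},
    "growth": {"growth_rate_true", "carrying_capacity", "noise_sd",
               "relative_rate_true"},
    "burden": {"genes", "r0"},
    "fixation": {"u", "s", "N", "target_frequency"},
}


def _check_keys(block: dict, schema_key: str, where: str) -> None:
    unknown = set(block) - _SCHEMA[schema_key]
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) in {where}: "
            f"{', '.join(sorted(unknown))}"
        )


class RunConfig(dict):
    """A validated run configuration (a dict with a checked schema)."""

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("configuration must be a mapping")
        _check_keys(raw, "", "the top level")
        for section in ("fluctuation", "junctions", "competition", "growth",
                        "burden", "fixation"):
            if section in raw:
                _check_keys(raw[section], section, f"section '{section}'")
        for i, region in enumerate(raw.get("regions", [])):
            _check_keys(region, "regions[]", f"regions[{i}]")
            if "name" not in region or "mu_true" not in region:
                raise ConfigError(f"regions[{i}] needs 'name' and 'mu_true'")
        if not raw.get("regions"):
            raise ConfigError("configuration must define at least one region")
        return cls(raw)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def load_demo_config() -> RunConfig:
    """The demo configuration shipped with the package."""
    text = resources.files("deletometer").joinpath("data/demo.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))


def _region_sim_config(cfg: RunConfig, region: dict, seed: int) -> SimulationConfig:
    fluct = cfg.get("fluctuation", {})
    junc = cfg.get("junctions", {})
    comp = cfg.get("competition", {})
    growth = cfg.get("growth", {})
    kwargs: dict = {"seed": seed, "mu_true": float(region["mu_true"])}
    for key in ("deletable_left_kbp", "deletable_right_kbp"):
        if key in region:
            kwargs[key] = float(region[key])
    int_keys = {"n_cultures", "n_cycles", "events_per_timepoint",
                "genome_length_bp"}
    for src, keys in (
        (fluct, ("n_cultures", "N0", "Nt", "plating_fraction", "min_deletion_kbp")),
        (junc, ("genome_length_bp",)),
        (comp, ("s_true", "n_cycles", "events_per_timepoint",
                "generations_per_cycle")),
        (growth, ("growth_rate_true", "carrying_capacity", "noise_sd")),
    ):
        for key in keys:
            if key in src:
                # YAML scalars may arrive as strings (e.g. "1.0e6")
                kwargs[key] = (int(float(src[key])) if key in int_keys
                               else float(src[key]))
    return SimulationConfig(**kwargs)


def run_pipeline(cfg: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full simulate -> estimate -> report pass.

    Returns a dict of output paths. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg.get("seed", 0) if seed is None else seed)
    artifacts: dict[str, Path] = {}

    stage = "rates"
    try:
        rate_rows = []
        junction_reports: list[jn.JunctionReport] = []
        for i, region in enumerate(cfg["regions"]):
            rseed = root_seed + 1000 * i
            sim = _region_sim_config(cfg, region, rseed)
            name = region["name"]

            exp = syn.simulate_fluctuation_cultures(sim)
            exp.region = name
            dio.write_fluctuation(exp, out / f"fluctuation_{name}.tsv")

            estimates: dict[str, fl.RateEstimate | None] = {}
            for method, fn in (("p0", fl.estimate_rate_p0),
                               ("median", fl.estimate_rate_median)):
                try:
                    estimates[method] = fn(exp)
                except fl.FluctuationError as exc:
                    logger.warning("region %s: %s method unavailable: %s",
                                   name, method, exc)
                    estimates[method] = None
            chosen = estimates["median"] or estimates["p0"]
            if chosen is None:
                raise PipelineError(
                    f"stage rates: no estimator applicable for region {name}"
                )

            stage = "junctions"
            marker = sim.genome_length_bp // 2
            n_events = int(cfg.get("junctions", {}).get("n_events", 30))
            max_scan = int(cfg.get("junctions", {}).get("max_scan", 50))
            events = syn.simulate_deletion_events(
                sim, marker, n_events=n_events, chrom=name
            )
            genomes: dict[str, str] = {}
            placed: list[jn.DeletionEvent] = []
            rng = np.random.default_rng([6, rseed])
            for j, ev in enumerate(events):
                h = sim.homology_lengths[j % len(sim.homology_lengths)]
                g = syn.random_genome(sim.genome_length_bp, rng)
                chrom_j = f"{name}_del{j + 1}"
                ev_j = jn.DeletionEvent(chrom=chrom_j, start=ev.start,
                                        end=ev.end, name=ev.name)
                genomes[chrom_j] = syn.plant_junction(
                    g, ev_j, h, seed=rseed + j
                )
                placed.append(ev_j)
            dio.write_deletions(placed, out / f"deletions_{name}.bed")
            dio.write_genome(genomes, out / f"genomes_{name}.fa")
            for ev in placed:
                junction_reports.append(
                    jn.find_junction_homology(genomes[ev.chrom], ev, max_scan)
                )

            stage = "rates"
            left = [(marker - ev.start) / 1000.0 for ev in placed]
            right = [(ev.end - marker) / 1000.0 for ev in placed]
            window = fl.estimate_window(left, right)
            largest = max(ev.size for ev in placed) / 1000.0
            norm = fl.normalize_rate(chosen, window, largest, region=name)
            rate_rows.append(
                {
                    "region": name,
                    "method": chosen.method,
                    "m": chosen.m,
                    "mu_raw": norm.mu_raw,
                    "se_mu": chosen.se_mu,
                    "mu_p0": estimates["p0"].mu if estimates["p0"] else math.nan,
                    "mu_median": (
                        estimates["median"].mu if estimates["median"] else math.nan
                    ),
                    "mu_per_kbp": norm.mu_per_kbp,
                    "mu_intrinsic_best": norm.mu_intrinsic_best,
                    "mu_intrinsic_lo": norm.mu_intrinsic_lo,
                    "mu_intrinsic_hi": norm.mu_intrinsic_hi,
                    "largest_deletion_kbp": largest,
                }
            )
        rates = pd.DataFrame(rate_rows)
        rates.to_csv(out / "rates.tsv", sep="\t", index=False)
        artifacts["rates"] = out / "rates.tsv"

        jn.junction_report_table(junction_reports).to_csv(
            out / "junctions.tsv", sep="\t", index=False
        )
        jn.summarize_junctions(junction_reports).to_csv(
            out / "junction_summary.tsv", sep="\t", index=False
        )
        artifacts["junctions"] = out / "junctions.tsv"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "fitness"
    try:
        base = _region_sim_config(cfg, cfg["regions"][0], root_seed + 77)
        traj = syn.simulate_competition(base)
        dio.write_competition(traj, out / "competition.tsv")
        sel = fit_selection_coefficient(traj)

        rel_true = float(cfg.get("growth", {}).get("relative_rate_true", 1.05))
        ref_curve = syn.simulate_growth_curve(base, replicate_id="reference")
        mut_cfg = SimulationConfig(
            **{**base.to_dict(),
               "growth_rate_true": base.growth_rate_true * rel_true,
               "seed": base.seed + 1}
        )
        mut_curve = syn.simulate_growth_curve(mut_cfg, replicate_id="mutant")
        dio.write_growth_curves([ref_curve, mut_curve], out / "growth.tsv")
        ref_fit = fit_growth_rate(ref_curve)
        mut_fit = fit_growth_rate(mut_curve)
        rel = relative_growth_rate(mut_fit, ref_fit)

        burden_cfg = cfg.get("burden", {})
        genes = GeneBurdenTable.from_records(
            [(g[0], float(g[1]), float(g[2]))
             for g in burden_cfg.get("genes", [])]
        )
        dio.write_gene_table(genes, out / "genes.tsv")
        s_burden = burden_selection(genes, r0=float(burden_cfg.get("r0", 1e9)))

        fitness = pd.DataFrame(
            [
                {"quantity": "s_competition", "value": sel.s, "se": sel.se_s},
                {"quantity": "relative_growth_rate", "value": rel,
                 "se": math.nan},
                {"quantity": "s_burden_predicted", "value": s_burden,
                 "se": math.nan},
            ]
        )
        fitness.to_csv(out / "fitness.tsv", sep="\t", index=False)
        artifacts["fitness"] = out / "fitness.tsv"
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "fixation"
    try:
        fxc = cfg.get("fixation", {})
        sc = fx.FixationScenario(
            N=float(fxc.get("N", 1e9)),
            u=float(fxc.get("u", 2.2e-8)),
            s=float(fxc.get("s", 0.054)),
            target_frequency=float(fxc.get("target_frequency", 0.5)),
        )
        det = fx.takeover_time_deterministic(sc)
        stoch = fx.simulate_serial_passage(sc, n_replicates=20,
                                           seed=root_seed + 99)
        pd.DataFrame(
            [
                {"model": "deterministic", "t50": det.t50,
                 "reached": det.reached, "sd_t50": math.nan,
                 "n_not_reached": 0},
                {"model": "stochastic", "t50": stoch.mean_t50,
                 "reached": stoch.reached, "sd_t50": stoch.sd_t50,
                 "n_not_reached": stoch.n_not_reached},
            ]
        ).to_csv(out / "takeover.tsv", sep="\t", index=False)
        artifacts["takeover"] = out / "takeover.tsv"
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    dio.write_provenance(out / "provenance.json", dict(cfg), root_seed)
    artifacts["provenance"] = out / "provenance.json"
    return {k: str(v) for k, v in artifacts.items()}
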