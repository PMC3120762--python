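"""End-to-end driver: simulate/load -> stats -> network -> fit -> select -> skyline.

Every stage writes its artifacts under the output directory with a
provenance block (package version, config hash, root seed), so the whole
artifact tree is regenerable from config + seed alone.  Stage failures
abort with a stage-tagged error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phylodeme import io as pio
from phylodeme.haplotypes import (collapse_haplotypes, haplotype_diversity,
                                  nucleotide_diversity, classify_segregating_sites,
                                  connection_limit)
from phylodeme.migration_fit import SamplerSettings, fit_all_scenarios
from phylodeme.model_select import rank_models
from phylodeme.network import build_network, write_graphml
from phylodeme.simulate import SimulationConfig, generate_dataset
from phylodeme.skyline import (ClockModel, SkylinePriors, SkylineSettings,
                               skyline_mcmc, skyline_plot)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "phylodeme_out"
    fasta: str | Path | None = None
    deme_map: str | Path | None = None
    simulation: SimulationConfig | None = None
    stages: tuple[str, ...] = ("stats", "network", "fit", "select", "skyline")
    deme_labels: tuple[str, ...] = ("F", "S", "A")
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    skyline_settings: SkylineSettings = field(default_factory=SkylineSettings)
    clock_rate: float = 4.28e-8
    priors: SkylinePriors = field(default_factory=SkylinePriors)
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            if self.fasta is None or self.deme_map is None:
                raise ValueError("either a simulation config or fasta+deme_map paths are required")
            for p in (self.fasta, self.deme_map):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    def provenance_source(self) -> dict:
        return {"fasta": str(self.fasta), "deme_map": str(self.deme_map),
                "simulated": self.simulation is not None,
                "stages": list(self.stages), "seed": self.seed,
                "clock_rate": self.clock_rate}


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("[%s] starting", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("[%s] failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("[%s] done", name)
            return out
        return wrapped
    return deco


@_stage("stats")
def run_stats(alignment, deme_map, out: Path, prov: dict) -> dict:
    table = collapse_haplotypes(alignment, deme_map)
    rows = []
    for deme in table.deme_labels:
        counts = table.counts[deme]
        n = int(counts.sum())
        rows.append({
            "deme": deme, "n": n,
            "n_haplotypes": int((counts > 0).sum()),
            "haplotype_diversity": haplotype_diversity(counts[counts > 0]) if n >= 2 else np.nan,
            "nucleotide_diversity": nucleotide_diversity(table, deme) if n >= 2 else np.nan,
        })
    total = table.total_counts()
    singles, pi_sites = classify_segregating_sites(alignment)
    rows.append({"deme": "ALL", "n": int(total.sum()),
                 "n_haplotypes": len(table.haplotype_ids),
                 "haplotype_diversity": haplotype_diversity(total),
                 "nucleotide_diversity": nucleotide_diversity(table)})
    df = pd.DataFrame(rows)
    df.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.6g")
    summary = {"provenance": prov, "n_haplotypes": len(table.haplotype_ids),
               "singleton_mutations": singles, "parsimony_informative_sites": pi_sites,
               "locus_length": table.locus_length,
               "clean_columns": int(len(table.included_columns))}
    pio.write_json(out / "stats.json", summary)
    return {"table": table, "summary": summary}


@_stage("network")
def run_network(table, out: Path) -> dict:
    limit = connection_limit(max(len(table.included_columns), 1), 0.95)
    net = build_network(table, limit)
    write_graphml(net, out / "network.graphml")
    return {"network": net, "limit": limit,
            "n_components": len(net.components())}


@_stage("fit")
def run_fit(alignment, deme_map, cfg: PipelineConfig, out: Path, prov: dict):
    settings = SamplerSettings(**{**cfg.sampler.__dict__, "seed": cfg.seed})
    fits, table = fit_all_scenarios(alignment, deme_map, settings, cfg.deme_labels)
    pio.write_json(out / "fits.json",
                   {"provenance": prov, "fits": [f.to_dict() for f in fits]})
    table.to_tsv(out / "model_table.tsv")
    return {"fits": fits, "table": table}


@_stage("select")
def run_select(rows, out: Path, prov: dict):
    table = rank_models(rows)
    table.to_tsv(out / "model_selection.tsv")
    pio.write_json(out / "model_selection.json",
                   {"provenance": prov, **table.to_dict()})
    return {"table": table}


@_stage("skyline")
def run_skyline(alignment, cfg: PipelineConfig, out: Path, prov: dict):
    settings = SkylineSettings(**{**cfg.skyline_settings.__dict__, "seed": cfg.seed + 77})
    post = skyline_mcmc(alignment, ClockModel(cfg.clock_rate), cfg.priors, settings)
    pio.write_json(out / "skyline.json", {"provenance": prov, **post.to_dict()})
    t, med, lo, hi = post.ne_grid()
    pd.DataFrame({"years_bp": t, "ne_median": med, "ne_lo95": lo, "ne_hi95": hi}) \
        .to_csv(out / "skyline_trajectory.tsv", sep="\t", index=False, float_format="%.6g")
    skyline_plot(post, out / "skyline.png")
    return {"posterior": post}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the per-stage results."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = pio.provenance(cfg.provenance_source(), cfg.seed)
    results: dict = {}
    if cfg.simulation is not None:
        logger.info("[simulate] generating synthetic dataset")
        alignment, deme_map, truth = generate_dataset(cfg.simulation, out)
        results["truth"] = truth
    else:
        alignment = pio.read_fasta(cfg.fasta)
        deme_map = pio.check_consistency(alignment, pio.read_deme_map(cfg.deme_map))
    table = None
    if "stats" in cfg.stages:
        res = run_stats(alignment, deme_map, out, prov)
        table = res["table"]
        results["stats"] = res["summary"]
    if "network" in cfg.stages:
        if table is None:
            table = collapse_haplotypes(alignment, deme_map)
        results["network"] = {k: v for k, v in run_network(table, out).items()
                              if k != "network"}
    if "fit" in cfg.stages:
        res = run_fit(alignment, deme_map, cfg, out, prov)
        results["fit"] = [f.to_dict() for f in res["fits"]]
        if "select" in cfg.stages:
            sel = run_select([{"scenario": f.scenario, "k": f.k, "LnL": f.lnl}
                              for f in res["fits"]], out, prov)
            results["select"] = sel["table"].to_dict()
    if "skyline" in cfg.stages:
        res = run_skyline(alignment, cfg, out, prov)
        results["skyline"] = res["posterior"].to_dict()
    pio.write_json(out / "pipeline_summary.json", {"provenance": prov, **{
        k: v for k, v in results.items() if k != "fit"}})
    return results
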