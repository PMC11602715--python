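"""End-to-end pipeline orchestration over the library stages.

``run_pipeline`` executes synth -> qc -> time trees -> summary statistics ->
ABC -> Gibbs on one synthetic pair at the scale set by the
:class:`~clonefate.config.PipelineConfig`, writing per-stage outputs, a
summary report and a manifest with seeds and checksums.  Stages whose outputs
already exist are skipped when ``resume`` is set.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc_inference import PriorSpec, abc_reject, run_reference_table
from .config import PipelineConfig, RunManifest, config_hash, stage_seeds
from .gibbs import clone_fractions, estimate_error_rates, gibbs_run, sdi
from .qc import peak_vaf_purity
from .readcounts import TargetedCounts
from .sumstats import EpochDefinition, engraftment_stats13, mntd, mpd
from .synth import emit_colony_reads, emit_targeted_reads, make_scenario
from .treecore import write_newick

__all__ = ["run_pipeline"]


def run_pipeline(cfg: PipelineConfig, seed: int = 0, outdir="pipeline_out",
                 resume: bool = False) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest = RunManifest(__version__, seed, seeds, config_hash(cfg))
    summary: dict = {}

    # --- synth -------------------------------------------------------------
    t0 = time.time()
    scenario = make_scenario(cfg.pair, seed=seeds["synth"],
                             rate_per_year=cfg.rate_per_year,
                             birth_burden=cfg.birth_burden)
    colony, colony_truth = emit_colony_reads(scenario, depth=cfg.colony_depth,
                                             seed=seeds["synth"] + 1)
    targeted, controls, _ = emit_targeted_reads(
        scenario, depth=cfg.targeted_depth, panel_fraction=cfg.panel_fraction,
        seed=seeds["synth"] + 2)
    write_newick(scenario.pair.combined_tree, outdir / "combined.time.nwk")
    write_newick(scenario.combined_molecular, outdir / "combined.molecular.nwk")
    manifest.time_stage("synth", t0)
    summary["n_colonies"] = len(colony.samples)
    summary["n_mutations"] = len(colony.mutations)

    # --- qc ----------------------------------------------------------------
    t0 = time.time()
    purity = {
        s: peak_vaf_purity(colony.variant[s].to_numpy(), colony.depth[s].to_numpy())
        for s in colony.samples
    }
    excluded = [s for s, r in purity.items() if r.status == "excluded"]
    summary["colonies_excluded_purity"] = len(excluded)
    summary["impure_injected"] = len(colony_truth["impure"])
    manifest.time_stage("qc", t0)

    # --- time trees and statistics ----------------------------------------
    t0 = time.time()
    donor_tree, recip_tree = scenario.pair.donor_tree, scenario.pair.recipient_tree
    epochs = EpochDefinition.from_preset("original", cfg.pair.donor_age_hct)
    obs_stats = engraftment_stats13(donor_tree, recip_tree, epochs)
    obs_stats.to_frame("value").to_csv(outdir / "observed_stats.tsv", sep="\t")
    summary["mpd_donor"] = round(mpd(donor_tree), 3)
    summary["mpd_recipient"] = round(mpd(recip_tree), 3)
    summary["mntd_recipient"] = round(mntd(recip_tree), 3)
    manifest.time_stage("sumstats", t0)

    # --- ABC ---------------------------------------------------------------
    t0 = time.time()
    spec = PriorSpec(
        log10_ntrans=(2.7, float(np.log10(cfg.pair.n_hsc))),
        n_hsc_fixed=cfg.pair.n_hsc,
    )
    ref = run_reference_table(spec, cfg.pair, cfg.abc_n_sims, seed=seeds["abc"])
    res = abc_reject(obs_stats, ref.stats["original"], ref.params,
                     quantile=cfg.abc_quantile)
    post = res.posterior_summary("log10_ntrans")
    summary["log10_ntrans_true"] = round(float(np.log10(cfg.pair.n_trans)), 3)
    summary["log10_ntrans_posterior"] = {k: round(v, 3) for k, v in post.items()}
    manifest.time_stage("abc", t0)

    # --- Gibbs -------------------------------------------------------------
    t0 = time.time()
    targeted.error_rates = estimate_error_rates(controls)
    sample = "recipient_gran"
    chain = gibbs_run(scenario.combined_molecular, targeted, sample=sample,
                      iterations=cfg.gibbs_iterations, burn_in=cfg.gibbs_burn_in,
                      thin=cfg.gibbs_thin, sigma=cfg.gibbs_sigma,
                      seed=seeds["gibbs"])
    chain.summary().to_csv(outdir / "gibbs_posterior.tsv", sep="\t",
                           index_label="mutation_id")
    info, draws = clone_fractions(chain, scenario.combined_molecular,
                                  cut=cfg.clone_cut)
    info.to_csv(outdir / "clone_fractions.tsv", sep="\t", index=False)
    if draws:
        h = sdi(draws)
        summary["sdi_recipient_gran"] = {
            "median": round(float(np.nanmedian(h)), 3),
            "n_clones": len(draws),
        }
    manifest.time_stage("gibbs", t0)

    # --- report ------------------------------------------------------------
    for name in ("combined.time.nwk", "combined.molecular.nwk",
                 "observed_stats.tsv", "gibbs_posterior.tsv",
                 "clone_fractions.tsv"):
        manifest.add_output(name, outdir / name)
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest.write(outdir / "manifest.json")
    return {"summary": summary, "manifest": manifest, "outdir": outdir}
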