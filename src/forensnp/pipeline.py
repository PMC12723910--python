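"""Umbrella pipeline: simulate -> call -> match -> concordance -> metrics.

Each run writes its artifact tables plus a manifest recording the config
hash, seed, package version and per-stage record counts, so two runs of
the same configuration can be compared file by file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as fio
from .assaystats import call_rate, summarize_run
from .calling import call_sample
from .concordance import pairwise_concordance_matrix
from .config import PipelineConfig
from .matching import pairwise_match_matrix, select_snps
from .panel import add_replicates, build_panel, simulate_individuals
from .sim import simulate_reads

logger = logging.getLogger(__name__)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write all artifact tables under ``out_dir``.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Any stage failure propagates with the stage named in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "stages": {},
    }

    logger.info("stage simulate: building panel and read tables")
    panel = build_panel(config.panel.n_autosomal, config.panel.n_y,
                        ("uniform", config.panel.freq_low, config.panel.freq_high),
                        seed=config.seed)
    truth = simulate_individuals(panel, config.samples.n,
                                 config.samples.sex_ratio, seed=config.seed + 1)
    for sid in config.samples.replicates_of:
        truth = add_replicates(truth, sid, config.samples.n_reps)
    sim = simulate_reads(truth, panel, config.simulate)
    fio.write_panel(panel, out / "panel.tsv")
    fio.write_reads(sim.reads, out / "reads.tsv")
    fio.write_truth(truth.dosage_frame(), out / "truth.tsv")
    fio.write_pairs(truth.pair_labels.to_frame(), out / "pairs.tsv")
    manifest["stages"]["simulate"] = {
        "markers": len(panel), "samples": len(truth.individuals),
        "read_rows": len(sim.reads),
    }

    logger.info("stage call: threshold genotyping")
    sex_of = {ind.sample_id: ind.sex for ind in truth.individuals}
    callsets = [
        call_sample(tab, panel, config.calling, sex=sex_of[sid], sample_id=sid)
        for sid, tab in sim.iter_samples()
    ]
    fio.write_calls(callsets, out / "calls.tsv")
    manifest["stages"]["call"] = {
        "callsets": len(callsets),
        "typed": int(sum(cs.n_typed for cs in callsets)),
    }

    logger.info("stage match: pairwise direct-match LRs")
    markers = select_snps(sim.reads, panel, config.n_select)
    matches = pairwise_match_matrix(sim.reads, panel, markers,
                                    config.match_error, config.match_rules)
    matches.to_csv(out / "matches.tsv", sep="\t", index=False,
                   lineterminator="\n")
    manifest["stages"]["match"] = {
        "markers_selected": len(markers), "pairs": len(matches)}

    logger.info("stage concordance: pairwise call agreement")
    conc = pairwise_concordance_matrix(callsets)
    conc.to_csv(out / "concordance.tsv", sep="\t", index=False,
                lineterminator="\n")
    manifest["stages"]["concordance"] = {"pairs": len(conc)}

    logger.info("stage metrics: call rates and run summaries")
    rate_rows = []
    for cs in callsets:
        r = call_rate(cs, panel, sex_of[cs.sample_id])
        rate_rows.append((r.sample_id, r.n_typed, r.n_targetable, r.rate))
    rates = pd.DataFrame(rate_rows, columns=["sample_id", "n_typed",
                                             "n_targetable", "rate"])
    run_rows = []
    for _, rec in sim.bookkeeping.iterrows():
        m = summarize_run(rec)
        run_rows.append(dataclasses.asdict(m))
    metrics = rates.merge(pd.DataFrame(run_rows), on="sample_id")
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False,
                   lineterminator="\n")
    manifest["stages"]["metrics"] = {"samples": len(metrics)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
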