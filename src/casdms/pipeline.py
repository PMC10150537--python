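"""Stage orchestration: simulate -> count -> score, with a structured run log.

Given one validated :class:`~casdms.config.RunConfig` and a seed, the
pipeline forks a deterministic RNG stream per stage, runs the requested
stages in dependency order, and writes TSV/JSON artifacts whose bytes depend
only on the config and seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calling import CountTable, meta_from_ids
from .config import RunConfig
from .enrichment import call_hits, paired_design, score_screen
from .genotyping import GenotypeThresholds, classify_genotype, summarize_targets
from .specificity import (
    binding_energy,
    cleavage_score,
    energy_to_pwm,
    enumerate_mismatch_library,
    fit_energy_model,
    harmonic_weights,
    plot_logo,
    write_meme,
)
from .synthetic import (
    EffectConfig,
    random_spec_truth,
    simulate_plant_alleles,
    simulate_screen,
    simulate_specseq,
)


@dataclass
class RunLog:
    events: list[dict] = field(default_factory=list)

    def log(self, stage: str, event: str, **fields) -> None:
        self.events.append(
            {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, "event": event, **fields}
        )

    def write(self, path) -> None:
        io.write_json(self.events, path)


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Fork one config seed into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_screen_stage(config: RunConfig, out_dir: Path, seed: int, log: RunLog) -> dict:
    cfg = config.screen
    log.log("screen", "begin", seed=seed)
    sim = simulate_screen(
        n_codons=cfg.n_codons,
        effect_config=EffectConfig(
            cfg.frac_beneficial, cfg.frac_deleterious, cfg.frac_null, cfg.effect_scale
        ),
        n_rounds=cfg.n_rounds,
        sequenced_rounds=cfg.sequenced_rounds,
        n_replicates=cfg.n_replicates,
        depth=cfg.depth,
        bottleneck=cfg.bottleneck,
        seed=seed,
    )
    cdict = config.model_dump()
    counts_path = out_dir / "counts.tsv"
    io.write_tsv(io.counts_to_long(sim.table.counts), counts_path, cdict, index=False)
    truth_path = out_dir / "effects_truth.tsv"
    io.write_tsv(sim.effects.weights.rename("w").to_frame(), truth_path, cdict)
    log.log(
        "screen", "end", n_variants=len(sim.variants), n_samples=len(sim.table.samples)
    )
    return {"sim": sim, "counts": counts_path, "truth": truth_path}


def run_enrich_stage(
    config: RunConfig, table: CountTable, out_dir: Path, log: RunLog
) -> dict:
    cfg = config.enrich
    log.log("enrich", "begin", n_rows=len(table.counts))
    reps = tuple(
        sorted(
            {
                int(c.split("_")[0][3:])
                for c in table.counts.columns
                if c.startswith("rep")
            }
        )
    )
    design = paired_design(reps, cfg.pre_round, cfg.post_round)
    result = score_screen(
        table,
        design,
        alpha=cfg.pseudocount,
        min_count=cfg.min_count,
        level=cfg.level,
        min_syn_anchors=cfg.min_syn_anchors,
    )
    cdict = config.model_dump()
    scores_path = out_dir / "scores.tsv"
    io.write_tsv(result.records, scores_path, cdict)
    hits = call_hits(result)
    hits_path = out_dir / "hits.tsv"
    io.write_tsv(hits, hits_path, cdict)
    summary = result.summary()
    io.write_json(summary, out_dir / "enrich_summary.json")
    log.log("enrich", "end", **{k: v for k, v in summary.items() if k != "offsets"})
    return {"result": result, "scores": scores_path, "hits": hits_path}


def run_specseq_stage(config: RunConfig, out_dir: Path, seed: int, log: RunLog) -> dict:
    cfg = config.specseq
    log.log("specseq", "begin", seed=seed)
    lib = enumerate_mismatch_library(
        cfg.target_seq, cfg.k_max, mode=cfg.mode, quota_per_k=cfg.quota_per_k, seed=seed
    )
    truth = random_spec_truth(
        cfg.target_seq, seed=seed, cleavage_rate_scale=cfg.cleavage_rate_scale
    )
    counts = simulate_specseq(truth, lib.sequences, cfg.depth, mu=cfg.mu, seed=seed + 1)
    cdict = config.model_dump()
    artifacts = {}
    for assay, scorer, fracs in (
        ("binding", binding_energy, ("bound", "unbound")),
        ("cleavage", cleavage_score, ("mock", "cleaved")),
    ):
        scores = scorer(counts.counts, cfg.target_seq)
        model = fit_energy_model(
            scores, cfg.target_seq, weights=harmonic_weights(counts.counts, fracs)
        )
        matrix_path = out_dir / f"{assay}_energy.tsv"
        io.write_tsv(model.matrix, matrix_path, cdict)
        write_meme(energy_to_pwm(model), out_dir / f"{assay}.meme", name=assay)
        plot_logo(model, out_dir / f"{assay}_logo.png", title=assay)
        io.write_json(
            {"assay": assay, "rmse": model.rmse, "n_obs": model.n_obs},
            out_dir / f"{assay}_fit.json",
        )
        artifacts[assay] = {"model": model, "matrix": matrix_path}
    log.log("specseq", "end", n_library=len(lib))
    return artifacts


def run_plants_stage(config: RunConfig, out_dir: Path, seed: int, log: RunLog) -> dict:
    cfg = config.plants
    log.log("plants", "begin", seed=seed)
    sim = simulate_plant_alleles(
        n_plants=cfg.n_plants,
        profile=cfg.profile,
        chimeric_noise=cfg.chimeric_noise,
        depth=cfg.depth,
        seed=seed,
    )
    g = config.genotype
    thresholds = GenotypeThresholds(
        g.min_depth, g.major_allele, g.wt_call, g.homozygous_allele,
        g.wt_absent, g.mono_wt_low, g.mono_wt_high,
    )
    calls = [classify_genotype(t, thresholds) for t in sim.tables]
    cdict = config.model_dump()
    alleles = pd.DataFrame(
        [
            {
                "plant_id": t.plant_id,
                "target_id": t.target_id,
                "allele": a.descriptor,
                "freq": a.frequency,
                "depth": t.read_depth,
            }
            for t in sim.tables
            for a in t.alleles
        ]
    )
    io.write_tsv(alleles, out_dir / "alleles.tsv", cdict, index=False)
    calls_df = pd.DataFrame(
        [
            {
                "plant_id": c.plant_id,
                "target_id": c.target_id,
                "genotype": c.genotype,
                "indel_frequency": c.indel_frequency,
                "truth": label,
            }
            for c, label in zip(calls, sim.labels)
        ]
    )
    io.write_tsv(calls_df, out_dir / "genotype_calls.tsv", cdict, index=False)
    summary = summarize_targets(calls, sim.tables)
    io.write_tsv(summary, out_dir / "target_summary.tsv", cdict, index=False)
    log.log("plants", "end", n_plants=cfg.n_plants)
    return {"sim": sim, "calls": calls, "summary": summary}


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> dict:
    """Run simulate -> count -> enrich (plus specseq and plant stages) and
    write all artifacts under ``out_dir``. Identical config and seed produce
    byte-identical TSV outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    s_screen, s_spec, s_plants, _ = stage_seeds(seed)
    log = RunLog()
    artifacts: dict = {}
    try:
        screen = run_screen_stage(config, out_dir, s_screen, log)
        artifacts.update(screen)
        artifacts.update(run_enrich_stage(config, screen["sim"].table, out_dir, log))
        artifacts["specseq"] = run_specseq_stage(config, out_dir, s_spec, log)
        artifacts["plants"] = run_plants_stage(config, out_dir, s_plants, log)
    finally:
        log.write(out_dir / "run_log.json")
    return artifacts


def count_table_from_tsv(path) -> CountTable:
    """Load a long-format (variant_id, sample, count) TSV as a CountTable,
    reconstructing variant metadata from the canonical ids."""
    long = io.read_tsv_table(path, required=["variant_id", "sample", "count"])
    counts = io.counts_from_long(long)
    meta = meta_from_ids(counts.index)
    level = "codon" if any("/" in str(i) for i in counts.index) else "aa"
    return CountTable(counts=counts, meta=meta, level=level)
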