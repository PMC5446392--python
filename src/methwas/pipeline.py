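"""End-to-end orchestration of the association pipeline on one run directory.

Stages run in fixed order: simulate -> preprocess -> methwas -> context ->
bsas -> stats. Identical config + seed gives byte-identical numeric
outputs; the run manifest records the seed and every threshold actually
used. Individual stages can be skipped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsas as bsas_mod
from . import context as context_mod
from . import diffmeth, io, preprocess, simulate, stats
from .types import Amplicon

__all__ = ["PipelineConfig", "run_pipeline", "make_amplicon"]


@dataclass
class PipelineConfig:
    """Thresholds (defaults are the modelled study's stated values) and scale."""

    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    batch_threshold: float = 1e-7  # paired batch-marker discovery
    batch_p_cut: float = 0.01  # batch-unstable probe filter
    covariate_alpha: float = 0.001  # FDR stopping level of covariate selection
    detection_p: float = 0.05  # Greedycut detection threshold
    mvp_threshold: float = 1e-7  # adjusted-p MVP call
    n_surrogates: int = 2
    normalize: str = "none"  # or "quantile"
    window_bp: int = 500
    min_abs_diff: float = 0.07
    min_q: int = 30
    q_fraction: float = 0.5
    min_identity: float = 0.9
    min_conversion: float = 0.9
    max_cpg_gap: float = 0.1
    min_reads: int = 1000
    alpha: float = 0.05
    # demo-scale replication stage
    bsas_samples_per_group: int = 3
    bsas_reads_per_sample: int = 1200
    skip_bsas: bool = False
    skip_context: bool = False
    seed: int = 0


def make_amplicon(rng: np.random.Generator, amplicon_id: str = "amp01", n_cpgs: int = 6, length: int = 120) -> Amplicon:
    """Random amplicon with ``n_cpgs`` CpGs and a cytosine-rich backbone.

    Plenty of non-CpG cytosines (roughly a quarter of the backbone) keep the
    per-read bisulfite conversion estimate fine-grained, as in real
    amplicons; the middle CpG is marked as the tested MVP.
    """
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    seq[seq == "C"] = "A"  # start cytosine-free, then place CpGs and lone Cs
    offs = np.sort(rng.choice(np.arange(5, length - 5, 4), size=n_cpgs, replace=False))
    for o in offs:
        seq[o], seq[o + 1] = "C", "G"
    protected = set(offs) | set(offs + 1)
    candidates = [i for i in range(2, length - 2) if i not in protected]
    rng.shuffle(candidates)
    placed = 0
    for o in candidates:
        if placed >= length // 4:
            break
        if seq[o + 1] != "G" and seq[o - 1] != "C" and o + 1 not in protected:
            seq[o] = "C"
            placed += 1
    s = "".join(seq)
    cpgs = tuple(int(o) for o in offs if s[o] == "C" and s[o + 1] == "G")
    return Amplicon(amplicon_id, s, cpgs, mvp_offset=cpgs[len(cpgs) // 2])


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage into ``outdir``; returns a summary dict (also on disk)."""
    out = io.ensure_dir(outdir)
    cfg = config
    cfg.cohort.seed = cfg.seed
    manifest = {"seed": cfg.seed, "thresholds": {k: v for k, v in asdict(cfg).items() if k != "cohort"}}
    summary: dict = {}

    # --- simulate + preprocess + methwas ---
    beta, sheet, annot, truth = simulate.generate_cohort(cfg.cohort)
    io.write_sample_sheet(sheet, out / "sample_sheet.csv")
    io.write_annotation(annot, out / "probe_annotation.tsv")

    batch = preprocess.paired_batch_test(beta, sheet, threshold=cfg.batch_threshold)
    if batch.candidates:
        batch = preprocess.select_covariate_markers(batch, beta, sheet, adjusted_alpha=cfg.covariate_alpha)
    summary["n_batch_candidates"] = len(batch.candidates)
    summary["n_batch_covariates"] = len(batch.selected_covariates)

    filtered, flog = preprocess.filter_probes(
        beta, annot, batch, batch_p_cut=cfg.batch_p_cut, detection_threshold=cfg.detection_p
    )
    filtered = preprocess.normalize_between_samples(filtered, method=cfg.normalize)
    summary["filter_removed"] = dict(flog.removed)

    spec = diffmeth.ModelSpec(n_surrogates=cfg.n_surrogates, mvp_threshold=cfg.mvp_threshold)
    mvp_table = diffmeth.run_methwas(filtered, sheet, spec, batch=batch, annot=annot)
    io.write_mvp_table(mvp_table, out / "mvp_table.tsv")
    summary["n_mvps"] = int(mvp_table["is_mvp"].sum())

    # --- context ---
    if not cfg.skip_context and mvp_table["is_mvp"].any():
        rep = context_mod.comethylation(
            mvp_table, mvp_table, annot, window_bp=cfg.window_bp, seed=cfg.seed
        )
        summary["comethylation"] = {"concordance": rep.concordance, "background": rep.bg_concordance, "p": rep.p}
        enr = context_mod.class_enrichment(mvp_table, mvp_table, annot, "promoter")
        summary["promoter_enrichment"] = {"mvp_fraction": enr.mvp_fraction, "bg_fraction": enr.bg_fraction, "p": enr.p}
        try:
            cand = context_mod.candidate_enrichment(mvp_table, mvp_table, annot)
            summary["candidate_enrichment"] = {"mvp_in": cand.mvp_in, "p": cand.p}
        except ValueError:
            summary["candidate_enrichment"] = None
    elif cfg.skip_context:
        summary["comethylation"] = "skipped"

    # --- bsas replication (demo scale) ---
    if not cfg.skip_bsas:
        rng = np.random.default_rng(cfg.seed + 1)
        amp = make_amplicon(rng)
        n_per = cfg.bsas_samples_per_group
        samples = [f"R{i:02d}" for i in range(2 * n_per)]
        groups = ["case"] * n_per + ["control"] * n_per
        ci = list(amp.cpg_offsets).index(amp.mvp_offset)
        truth_fracs = {}
        for s, g in zip(samples, groups):
            fr = np.full(len(amp.cpg_offsets), 0.5)
            fr[ci] = 0.35 if g == "case" else 0.55  # planted replication signal
            truth_fracs[s] = {amp.amplicon_id: fr}
        sim = simulate.generate_amplicon_reads(
            [amp], truth_fracs, n_reads=cfg.bsas_reads_per_sample, base_error=0.002, conversion_failure=0.01,
            seed=cfg.seed + 2,
        )
        io.write_fastq(sim.records, out / "reads.fastq.gz")
        io.write_panel([amp], out / "panel.fasta", out / "panel_cpgs.tsv")
        calls, blog, bsum = bsas_mod.run_bsas(
            sim.records, sim.barcode_map, [amp],
            min_q=cfg.min_q, min_qfrac=cfg.q_fraction, min_identity=cfg.min_identity,
            min_conversion=cfg.min_conversion, max_cpg_gap=cfg.max_cpg_gap, min_reads=cfg.min_reads,
        )
        calls.to_csv(out / "meth_calls.tsv", sep="\t", index=False)
        rsheet = pd.DataFrame(
            {"sample_id": samples, "group": groups, "sex": "F", "age": 3.5, "batch": "B0", "rebatch_of": "", "tissue": "blood"}
        )
        per_mvp, pooled = bsas_mod.compare_mvp_sites(calls, rsheet, [amp])
        per_mvp.to_csv(out / "mvp_replication.tsv", sep="\t", index=False)
        summary["bsas"] = {
            "filter_log": dict(blog.counts),
            "mvp_p": float(per_mvp["p"].iloc[0]) if len(per_mvp) else None,
            "pooled_p": pooled.get("p"),
        }
    else:
        manifest["skipped"] = manifest.get("skipped", []) + ["bsas"]

    # --- tissue correlation and penetrance ---
    tissue = simulate.generate_paired_tissue(seed=cfg.seed + 3)
    reg = stats.tissue_regression(tissue["blood"], tissue["lip"])
    summary["tissue_r2"] = reg.r_squared
    clones = simulate.generate_clones(seed=cfg.seed + 4)
    fracs: dict[str, list[float]] = {}
    for cs in clones:
        fracs.setdefault(cs.group, []).append(cs.methylation_fraction())
    h, p, _ = stats.compare_clone_groups(fracs)
    summary["penetrance_kw"] = {"H": h, "p": p}

    manifest["summary_keys"] = sorted(summary)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
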