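"""End-to-end orchestration: simulate -> genotype -> sweep -> annotate -> enrich.

A run is driven by one configuration mapping (YAML file or dict) and writes
every stage table plus a machine-readable ``summary.yaml`` into a run
directory. Rerunning the same configuration byte-reproduces all outputs.

Configuration keys (all optional except one input source)::

    seed: 7
    simulate: {n_cases: 23, n_controls: 14, n_loci: 12310, ...}
    inputs: {depth: depth.tsv, design: design.tsv, window_size: 800}
    genotype:
      source: truth | depth     # truth ranks the simulated loci directly
      gc_correct: false
      apply_qc: true
      ...
    sweep: {alpha: 0.01, variance_convention: sample}
    annotate: {genes: genes.gff3, dialect: gff3, gmt: pathways.gmt, flank: 0}

``genotype.source: truth`` is the QC-free mode: the sweep ranks exactly the
``n_loci`` simulated truth loci, with no genotyping or QC attrition, so the
top-quantile selection counts are exact functions of n_loci and alpha.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import __version__
from .enrichment import enrich, overlap_genes
from .genotyper import genotype_cohort, loci_from_spans
from .model import ConfigError, chrom_sort_key
from .sweep import SweepConfig, build_sweep_table, intersect_candidates
from .synthetic import SimulationConfig, simulate_cohort, simulate_depth, write_truth_table

log = logging.getLogger("cnvsweep")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def manhattan_table(sweep_table: pd.DataFrame, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Add cumulative genome coordinates for Manhattan-style display.

    Chromosomes are ordered naturally (chr2 before chr10, X last); the offset
    of each chromosome is the prefix sum of the preceding chromosome lengths
    (taken from ``chrom_lengths`` or the max locus end per chromosome).
    Output order and coordinates do not depend on input row order.
    """
    df = sweep_table.copy()
    chroms = sorted(df["chrom"].unique(), key=chrom_sort_key)
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom")["end"].max().to_dict()
    offsets: dict[str, int] = {}
    acc = 0
    for c in chroms:
        offsets[c] = acc
        acc += int(chrom_lengths[c])
    df = df.sort_values(
        ["chrom", "start"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    df["cum_pos"] = df["chrom"].map(offsets).astype(np.int64) + df["start"]
    return df


def run_all(config, outdir=None) -> dict:
    """Execute the full pipeline; returns the run summary (also on disk)."""
    cfg = _load_config(config)
    outdir = Path(outdir if outdir is not None else cfg.get("outdir", "cnvsweep_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {"cnvsweep_version": __version__}
    try:
        seed = int(cfg.get("seed", 0))
        summary["seed"] = seed
        gcfg = dict(cfg.get("genotype", {}))
        source = gcfg.pop("source", "depth")
        truth_df = None

        if "inputs" in cfg:
            stage = "inputs"
            inputs = cfg["inputs"]
            window_size = int(inputs.get("window_size", 800))
            depth = cio.read_depth_matrix(inputs["depth"], window_size)
            design = cio.read_design(inputs["design"])
            if source == "truth":
                raise ConfigError("genotype source 'truth' requires simulated inputs")
        else:
            stage = "simulate"
            sim = SimulationConfig(**{"seed": seed, **cfg.get("simulate", {})})
            truth_matrix, design, truth_df = simulate_cohort(sim)
            summary["n_loci_simulated"] = sim.n_loci
            summary["n_planted"] = int(truth_df["planted"].sum())
            cio.write_design(design, outdir / "design.tsv")
            write_truth_table(truth_df, outdir / "truth.tsv")
            if source == "truth":
                depth = None
            else:
                depth = simulate_depth(truth_matrix, sim)
                cio.write_depth_matrix(depth, outdir / "depth.tsv")
            log.info("simulated cohort: %d individuals, %d loci, %d planted",
                     sim.n_individuals, sim.n_loci, summary["n_planted"])

        stage = "genotype"
        if source == "truth":
            matrix = truth_matrix
        else:
            known = gcfg.pop("at_truth_loci", False)
            loci = loci_from_spans(depth, truth_matrix.loci) if (known and truth_df is not None) else None
            matrix = genotype_cohort(depth, loci=loci, **gcfg)
            cio.write_qc_report(matrix, outdir / "qc.tsv")
        cio.write_cnv_genotypes(matrix, outdir / "genotypes.tsv")
        cio.write_normalized_cn(matrix, outdir / "normalized_cn.tsv")
        summary["n_loci_genotyped"] = matrix.n_loci
        log.info("genotyped %d loci", matrix.n_loci)

        stage = "sweep"
        sweep_cfg = SweepConfig(**cfg.get("sweep", {}))
        table, sweep_summary = build_sweep_table(matrix, design, sweep_cfg)
        cio.write_sweep_table(table, outdir / "sweep_table.tsv")
        cio.write_sweep_table(
            manhattan_table(table).drop(columns="cum_pos"), outdir / "sweep_table_sorted.tsv"
        )
        summary.update(sweep_summary)
        vst_set = list(table.loc[table["candidate_vst"], "locus_id"])
        fst_set = list(table.loc[table["candidate_fst"], "locus_id"])
        both = intersect_candidates(vst_set, fst_set)
        summary["n_candidate_both"] = len(both)
        log.info("sweep: N_vst=%d N_fst=%d k=%d/%d intersection=%d",
                 summary["n_ranked_vst"], summary["n_ranked_fst"],
                 summary["k_vst"], summary["k_fst"], len(both))

        acfg = cfg.get("annotate", {})
        if acfg.get("genes"):
            stage = "annotate"
            genes = cio.read_gene_models(acfg["genes"], acfg.get("dialect", "gff3"))
            cand_loci = [l for l in matrix.loci if l.locus_id in set(both)]
            assignment, union = overlap_genes(cand_loci, genes, flank=int(acfg.get("flank", 0)))
            with open(outdir / "candidate_genes.tsv", "w", encoding="utf-8") as fh:
                fh.write("#locus_id\tgenes\n")
                for lid, gs in assignment.items():
                    fh.write(f"{lid}\t{','.join(gs)}\n")
            summary["n_candidate_genes"] = len(union)
            if acfg.get("gmt"):
                stage = "enrich"
                pathways = cio.read_gmt(acfg["gmt"])
                usable = [g for g in union if g in pathways.background]
                results = enrich(usable, pathways, cutoff=float(acfg.get("cutoff", 0.05)))
                cio.write_enrichment(results, outdir / "enrichment.tsv")
                summary["n_significant_pathways"] = int(results["significant"].sum())
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(summary), fh, sort_keys=True)
    return summary


def _plain(obj):
    """Coerce numpy scalars to plain python types for stable YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
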