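"""Candidate-locus gene annotation and hypergeometric pathway enrichment.

Genes are assigned to a candidate CNV locus when their intervals share at
least one base (both 1-based inclusive; an optional flank widens the locus).
Pathway over-representation of the resulting gene set is tested with the
exact upper-tail hypergeometric probability and Benjamini-Hochberg
correction across pathways.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import CNVLocus, GeneModel, PathwayMap, ValidationError


def overlap_genes(
    candidates: list[CNVLocus],
    genes: list[GeneModel],
    flank: int = 0,
) -> tuple[dict[str, tuple[str, ...]], list[str]]:
    """Map each candidate locus to the genes it overlaps (>= 1 shared base).

    Returns a dict locus_id -> sorted tuple of gene_ids, plus the sorted,
    deduplicated union gene set. Candidate chromosomes absent from the
    annotation trigger a warning, not an error.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree interval [start, end+1) covers the inclusive gene span
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    assignment: dict[str, tuple[str, ...]] = {}
    union: set[str] = set()
    missing_chroms: set[str] = set()
    for locus in candidates:
        tree = trees.get(locus.chrom)
        if tree is None:
            missing_chroms.add(locus.chrom)
            assignment[locus.locus_id] = ()
            continue
        hits = tree.overlap(max(1, locus.start - flank), locus.end + 1 + flank)
        ids = tuple(sorted({iv.data for iv in hits}))
        assignment[locus.locus_id] = ids
        union.update(ids)
    if missing_chroms:
        warnings.warn(
            f"candidate chromosomes absent from annotation: {sorted(missing_chroms)}",
            stacklevel=2,
        )
    return assignment, sorted(union)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (the correction used by enrich)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    candidate_genes,
    pathways: PathwayMap,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``candidate_genes`` against ``pathways``.

    For a pathway with K background genes, a candidate set of size n drawn
    from a background of size N, p is the exact probability of observing at
    least the k candidate genes found in the pathway. q is the
    Benjamini-Hochberg adjusted value across all tested pathways;
    ``significant`` flags q <= cutoff. Rows are sorted by p (ties by
    pathway_id).
    """
    candidates = frozenset(candidate_genes)
    if not pathways.pathways:
        raise ValidationError("no pathways to test")
    offenders = sorted(candidates - pathways.background)
    if offenders:
        raise ValidationError(f"candidate genes absent from background: {offenders}")
    n_bg = len(pathways.background)
    n_cand = len(candidates)
    rows = []
    for pid, members in pathways.pathways.items():
        big_k = len(members)
        k = len(candidates & members)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_cand))
        rows.append((pid, k, big_k, n_cand, n_bg, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["pathway_id", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= cutoff
    df = df.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)
    return df
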