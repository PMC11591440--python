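"""Per-locus population-differentiation statistics and candidate selection.

Two statistics are computed between the case and control groups:

* V_ST = (V_T - V_S) / V_T, where V_T is the variance of normalized copy
  number across all individuals pooled and V_S the population-size-weighted
  mean of the within-group variances (Redon-style CNV differentiation).
* Weir & Cockerham's F_ST estimator theta = a / (a + b + c) from the
  among-population (a), among-individual-within-population (b) and
  within-individual (c) variance components, on a biallelic encoding of the
  integer copy-number genotypes.

Candidates are the loci in the top alpha quantile of each statistic
(k = floor(alpha * N) of the N rankable loci, minimum 1), and the reported
selection threshold is the smallest selected score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CnvClass,
    CopyNumberMatrix,
    PopulationDesign,
    ValidationError,
)

SAMPLE = "sample"
POPULATION = "population"


@dataclass(frozen=True)
class SweepConfig:
    """Selection parameters: top-quantile fraction and variance convention."""

    alpha: float = 0.01
    tie_rule: str = "by_rank_order"
    variance_convention: str = SAMPLE

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.tie_rule != "by_rank_order":
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")
        if self.variance_convention not in (SAMPLE, POPULATION):
            raise ValueError(f"unknown variance convention {self.variance_convention!r}")


@dataclass(frozen=True)
class VstResult:
    v_total: float
    v_within: float
    vst: float  # NaN when undefined
    defined: bool


@dataclass(frozen=True)
class FstComponents:
    a: float
    b: float
    c: float
    theta: float  # NaN when undefined
    defined: bool


def _group_values(values: np.ndarray, design: PopulationDesign):
    values = np.asarray(values, dtype=float)
    if values.size != len(design.individuals):
        raise ValidationError("values length does not match design")
    if not np.isfinite(values).all():
        raise ValidationError("values must be finite")
    mask = design.case_mask
    g1, g2 = values[mask], values[~mask]
    if g1.size < 2 or g2.size < 2:
        raise ValidationError("each group needs at least 2 individuals")
    return g1, g2


def vst(values, design: PopulationDesign, convention: str = SAMPLE) -> VstResult:
    """V_ST of one locus from per-individual normalized copy numbers."""
    if convention not in (SAMPLE, POPULATION):
        raise ValueError(f"unknown variance convention {convention!r}")
    ddof = 1 if convention == SAMPLE else 0
    g1, g2 = _group_values(values, design)
    pooled = np.concatenate([g1, g2])
    v_t = float(np.var(pooled, ddof=ddof))
    v_s = float(
        (np.var(g1, ddof=ddof) * g1.size + np.var(g2, ddof=ddof) * g2.size)
        / pooled.size
    )
    if v_t == 0.0:
        return VstResult(v_total=0.0, v_within=v_s, vst=math.nan, defined=False)
    return VstResult(v_total=v_t, v_within=v_s, vst=(v_t - v_s) / v_t, defined=True)


# ------------------------------------------------------------------- F_ST

def cn_to_biallelic(icn, cnv_class: CnvClass) -> list[np.ndarray]:
    """Encode integer CN genotypes as biallelic alt-allele dosages {0, 1, 2}.

    Deletion loci: CN 2 -> 0 (ref/ref), CN 1 -> 1 (ref/alt), CN 0 -> 2
    (alt/alt). Duplication loci: CN 2 -> 0, CN 3 -> 1, CN >= 4 -> 2. A mixed
    locus is split into a deletion and a duplication sub-locus (each scored
    separately; the locus theta is the larger of the two), so the returned
    list has one encoding for pure loci and two for mixed loci.
    """
    icn = np.asarray(icn)
    if (icn < 0).any():
        raise ValidationError("integer copy numbers must be >= 0")
    if cnv_class == CnvClass.DELETION:
        if (icn > 2).any():
            raise ValidationError("deletion locus contains CN > 2")
        return [2 - icn]
    if cnv_class == CnvClass.DUPLICATION:
        if (icn < 2).any():
            raise ValidationError("duplication locus contains CN < 2")
        return [np.minimum(icn - 2, 2)]
    return [np.clip(2 - icn, 0, 2), np.clip(icn - 2, 0, 2)]


def _wc_components(n1, n2, p1, p2, h1, h2):
    """Weir & Cockerham (1984) two-population variance components.

    n_i: sample sizes; p_i: alt allele frequencies; h_i: observed
    heterozygote frequencies.
    """
    r = 2
    n = np.asarray([n1, n2], dtype=float)
    p = np.asarray([p1, p2], dtype=float)
    h = np.asarray([h1, h2], dtype=float)
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def fst_wc(genotypes, design: PopulationDesign) -> FstComponents:
    """Weir-Cockerham theta for one biallelic locus.

    ``genotypes`` are alt-allele dosages in {0, 1, 2} per individual, in the
    design's order.
    """
    g = np.asarray(genotypes)
    if not np.isin(g, [0, 1, 2]).all():
        raise ValidationError("genotype codes must be 0, 1 or 2")
    g1, g2 = _group_values(g, design)
    a, b, c = _wc_components(
        g1.size, g2.size,
        g1.mean() / 2, g2.mean() / 2,
        (g1 == 1).mean(), (g2 == 1).mean(),
    )
    denom = a + b + c
    if denom == 0.0:
        return FstComponents(a=a, b=b, c=c, theta=math.nan, defined=False)
    return FstComponents(a=a, b=b, c=c, theta=a / denom, defined=True)


def fst_for_locus(icn, cnv_class: CnvClass, design: PopulationDesign) -> FstComponents:
    """Locus-level theta: direct for pure loci, max over sub-loci for mixed."""
    results = [fst_wc(enc, design) for enc in cn_to_biallelic(icn, cnv_class)]
    defined = [res for res in results if res.defined]
    if not defined:
        return results[0]
    return max(defined, key=lambda res: res.theta)


# ------------------------------------------------------------- selection

def top_quantile(
    scores: pd.Series, alpha: float, tie_rule: str = "by_rank_order"
) -> tuple[list, float]:
    """Select the top alpha fraction of loci by score.

    ``scores`` is indexed by locus_id in genome order; NaN (undefined) scores
    are excluded from the ranked universe N. k = floor(alpha * N), at least
    1. Boundary ties are broken by ascending locus order. Returns the
    selected locus ids in genome order and the threshold (smallest selected
    score).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if tie_rule != "by_rank_order":
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    defined = scores.dropna()
    if defined.empty:
        raise ValidationError("no defined scores to rank")
    n = defined.size
    k = max(1, math.floor(alpha * n))
    order = np.lexsort((np.arange(n), -defined.to_numpy()))
    chosen_pos = np.sort(order[:k])
    selected = defined.iloc[chosen_pos]
    return list(selected.index), float(selected.min())


def intersect_candidates(set_vst, set_fst) -> list:
    """Exact intersection of the two candidate sets, in genome (first-set) order."""
    other = set(set_fst)
    return [locus for locus in set_vst if locus in other]


# ------------------------------------------------------- whole-table driver

def _vectorized_vst(ncn: np.ndarray, case_mask: np.ndarray, convention: str):
    ddof = 1 if convention == SAMPLE else 0
    v_t = np.var(ncn, axis=0, ddof=ddof)
    n1 = int(case_mask.sum())
    n2 = ncn.shape[0] - n1
    v1 = np.var(ncn[case_mask], axis=0, ddof=ddof)
    v2 = np.var(ncn[~case_mask], axis=0, ddof=ddof)
    v_s = (v1 * n1 + v2 * n2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(v_t > 0, (v_t - v_s) / np.where(v_t > 0, v_t, 1.0), np.nan)
    return out


def _vectorized_theta(codes: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """theta per locus for a (n_ind, n_loci) dosage matrix; NaN when undefined."""
    g1 = codes[case_mask]
    g2 = codes[~case_mask]
    n1, n2 = g1.shape[0], g2.shape[0]
    thetas = np.empty(codes.shape[1])
    p1 = g1.mean(axis=0) / 2
    p2 = g2.mean(axis=0) / 2
    h1 = (g1 == 1).mean(axis=0)
    h2 = (g2 == 1).mean(axis=0)
    r = 2
    n = np.array([n1, n2], dtype=float)
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return thetas


def build_sweep_table(
    matrix: CopyNumberMatrix,
    design: PopulationDesign,
    config: SweepConfig = SweepConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Compute V_ST and F_ST for every locus and flag top-quantile candidates.

    Returns the sweep table (locus_id, chrom, start, end, vst, fst,
    rank_vst, rank_fst, candidate_vst, candidate_fst, candidate_both) and a
    run summary with the ranked universe sizes, k, and selection thresholds.
    """
    if list(matrix.individuals) != list(design.individuals):
        design = design.reorder(matrix.individuals)
    case_mask = design.case_mask
    ids = [l.locus_id for l in matrix.loci]

    vst_vals = _vectorized_vst(matrix.ncn, case_mask, config.variance_convention)

    del_codes = np.clip(2 - matrix.icn, 0, 2)
    dup_codes = np.clip(matrix.icn - 2, 0, 2)
    theta_del = _vectorized_theta(del_codes, case_mask)
    theta_dup = _vectorized_theta(dup_codes, case_mask)
    classes = np.array([l.cnv_class.value for l in matrix.loci])
    with np.errstate(invalid="ignore"):
        theta_mixed = np.where(
            np.isnan(theta_del), theta_dup,
            np.where(np.isnan(theta_dup), theta_del, np.maximum(theta_del, theta_dup)),
        )
    fst_vals = np.where(
        classes == CnvClass.DELETION.value, theta_del,
        np.where(classes == CnvClass.DUPLICATION.value, theta_dup, theta_mixed),
    )

    table = pd.DataFrame(
        {
            "locus_id": ids,
            "chrom": [l.chrom for l in matrix.loci],
            "start": [l.start for l in matrix.loci],
            "end": [l.end for l in matrix.loci],
            "vst": vst_vals,
            "fst": fst_vals,
        }
    )

    summary: dict = {"n_loci": len(ids), "alpha": config.alpha}
    for stat in ("vst", "fst"):
        scores = pd.Series(table[stat].to_numpy(), index=ids)
        selected, threshold = top_quantile(scores, config.alpha, config.tie_rule)
        sel = set(selected)
        table[f"candidate_{stat}"] = [i in sel for i in ids]
        defined = scores.notna()
        ranks = np.full(len(ids), np.nan)
        dvals = scores[defined]
        order = np.lexsort((np.arange(dvals.size), -dvals.to_numpy()))
        rr = np.empty(dvals.size)
        rr[order] = np.arange(1, dvals.size + 1)
        ranks[defined.to_numpy()] = rr
        table[f"rank_{stat}"] = ranks
        summary[f"n_ranked_{stat}"] = int(defined.sum())
        summary[f"k_{stat}"] = len(selected)
        summary[f"threshold_{stat}"] = threshold
    table["candidate_both"] = table["candidate_vst"] & table["candidate_fst"]
    summary["n_candidate_both"] = int(table["candidate_both"].sum())
    table = table[
        ["locus_id", "chrom", "start", "end", "vst", "fst",
         "rank_vst", "rank_fst", "candidate_vst", "candidate_fst", "candidate_both"]
    ]
    return table, summary
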