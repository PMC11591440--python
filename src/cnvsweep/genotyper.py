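"""Read-depth CNV genotyping: normalization, locus definition, integer CN
calls, and silhouette/MAF quality control.

This is a deliberately transparent reimplementation of the population-scale
read-depth genotyping stage used by tools such as CNVcaller: per-individual
median normalization to a diploid baseline of 2, optional GC-bin correction,
run-length merging of aberrant windows into CNV loci, rounding to integer
copy numbers, and two locus-level QC metrics (silhouette coefficient over
copy-number classes and minor-class frequency).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CNVLocus,
    CopyNumberMatrix,
    GenomicWindow,
    LocusQC,
    ValidationError,
    WindowDepthMatrix,
    classify_cnv,
)

#: retention thresholds of the QC filter (loci must reach both)
SILHOUETTE_MIN = 0.6
MAF_MIN = 0.05


def normalize_depth(
    depth: WindowDepthMatrix, gc_correct: bool = False, gc_bins: int = 20
) -> np.ndarray:
    """Normalized copy number: 2 * depth / per-individual autosomal median.

    With ``gc_correct``, windows are grouped into ``gc_bins`` equal-width GC
    bins and each value is further divided by the ratio of its individual's
    bin median to that individual's global (autosomal) median.
    """
    auto = depth.autosomal_mask()
    if not auto.any():
        raise ValidationError("no autosomal windows to normalize against")
    med = np.median(depth.depth[:, auto], axis=1)
    for i, m in enumerate(med):
        if m <= 0:
            raise ValidationError(
                f"individual {depth.individuals[i]!r} has non-positive median depth"
            )
    ncn = 2.0 * depth.depth / med[:, None]
    if gc_correct:
        gcs = np.array([w.gc for w in depth.windows])
        bins = np.clip((gcs * gc_bins).astype(int), 0, gc_bins - 1)
        global_med = np.median(ncn[:, auto], axis=1)
        for b in range(gc_bins):
            in_bin = bins == b
            if not in_bin.any():
                continue
            bin_med = np.median(ncn[:, in_bin], axis=1)
            ratio = np.where(bin_med > 0, bin_med / global_med, 1.0)
            ncn[:, in_bin] = ncn[:, in_bin] / ratio[:, None]
    return ncn


@dataclass(frozen=True)
class DefinedLocus:
    """A CNV locus plus the indices of its member windows."""

    locus: CNVLocus
    window_indices: tuple[int, ...]


def define_loci(
    ncn: np.ndarray,
    windows: list[GenomicWindow],
    aberration_low: float = 1.5,
    aberration_high: float = 2.5,
    min_carrier_freq: float = 0.05,
    cn_max: int = 8,
) -> list[DefinedLocus]:
    """Merge runs of adjacent aberrant windows into CNV loci.

    A window is aberrant when at least ``min_carrier_freq`` of individuals
    have normalized CN outside [aberration_low, aberration_high]. Maximal
    runs of coordinate-adjacent aberrant windows on one chromosome become
    loci; the locus class is derived from the mean normalized CN of its
    member windows.
    """
    ncn = np.asarray(ncn)
    if ncn.shape[1] != len(windows):
        raise ValidationError("ncn columns do not match windows")
    outside = (ncn < aberration_low) | (ncn > aberration_high)
    aberrant = outside.mean(axis=0) >= min_carrier_freq

    result: list[DefinedLocus] = []
    run: list[int] = []

    def flush(run: list[int]):
        if not run:
            return
        chrom = windows[run[0]].chrom
        start = windows[run[0]].start
        end = windows[run[-1]].end
        locus_ncn = ncn[:, run].mean(axis=1)
        icn = call_integer_cn(locus_ncn, cn_max=cn_max)
        result.append(
            DefinedLocus(
                locus=CNVLocus(
                    locus_id=f"{chrom}:{start}-{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_class=classify_cnv(icn),
                ),
                window_indices=tuple(run),
            )
        )

    for idx, w in enumerate(windows):
        if not aberrant[idx]:
            flush(run)
            run = []
            continue
        if run and (
            windows[run[-1]].chrom != w.chrom or w.start != windows[run[-1]].end + 1
        ):
            flush(run)
            run = []
        run.append(idx)
    flush(run)
    return result


def call_integer_cn(ncn: np.ndarray, cn_max: int = 8) -> np.ndarray:
    """Round normalized CN to integers, half away from zero, clip to [0, cn_max]."""
    ncn = np.asarray(ncn, dtype=float)
    if (ncn < 0).any():
        raise ValidationError("normalized copy numbers must be >= 0")
    return np.clip(np.floor(ncn + 0.5).astype(np.int64), 0, cn_max)


def silhouette_coefficient(values: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette of the integer-CN clustering of one locus, on 1-D distances.

    Clusters are the distinct integer copy-number classes. For individual i
    in a class of size >= 2, a_i is the mean |v_i - v_j| to its own class and
    b_i the smallest mean distance to any other class; s_i = (b_i - a_i) /
    max(a_i, b_i) (0 when both are 0). Singletons contribute s_i = 0, and a
    locus with a single class scores 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    if n < 2:
        raise ValidationError("silhouette needs at least 2 individuals")
    classes = np.unique(labels)
    if classes.size == 1:
        return 0.0
    dist = np.abs(values[:, None] - values[None, :])
    onehot = (labels[:, None] == classes[None, :]).astype(float)  # (n, k)
    counts = onehot.sum(axis=0)  # (k,)
    sums = dist @ onehot  # (n, k): total distance from i to each class
    own_col = np.searchsorted(classes, labels)
    own_count = counts[own_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), own_col] / (own_count - 1)  # self-distance is 0
        mean_to = sums / counts[None, :]
    mean_to[np.arange(n), own_col] = np.inf
    b = mean_to.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s = np.where(own_count < 2, 0.0, s)  # singletons contribute 0
    return float(s.mean())


def minor_class_frequency(icn: np.ndarray) -> float:
    """Frequency of the non-modal integer CN classes, folded to [0, 0.5]."""
    icn = np.asarray(icn)
    _, counts = np.unique(icn, return_counts=True)
    f_modal = counts.max() / icn.size
    return float(min(1.0 - f_modal, 0.5))


def locus_qc(
    ncn: np.ndarray,
    icn: np.ndarray,
    silhouette_min: float = SILHOUETTE_MIN,
    maf_min: float = MAF_MIN,
) -> LocusQC:
    s = silhouette_coefficient(ncn, icn)
    maf = minor_class_frequency(icn)
    return LocusQC(silhouette=s, maf=maf, passed=bool(s >= silhouette_min and maf >= maf_min))


def qc_filter(
    matrix: CopyNumberMatrix,
    silhouette_min: float = SILHOUETTE_MIN,
    maf_min: float = MAF_MIN,
) -> CopyNumberMatrix:
    """Retain loci with silhouette >= silhouette_min and MAF >= maf_min.

    QC metrics are recomputed from the matrix, so the operation is
    idempotent. Returns a matrix of passing loci with their flags recorded.
    """
    qcs = [
        locus_qc(matrix.ncn[:, j], matrix.icn[:, j], silhouette_min, maf_min)
        for j in range(matrix.n_loci)
    ]
    keep = [j for j, qc in enumerate(qcs) if qc.passed]
    out = matrix.subset_loci(keep)
    out.qc = [qcs[j] for j in keep]
    return out


def genotype_cohort(
    depth: WindowDepthMatrix,
    gc_correct: bool = False,
    gc_bins: int = 20,
    aberration_low: float = 1.5,
    aberration_high: float = 2.5,
    min_carrier_freq: float = 0.05,
    cn_max: int = 8,
    silhouette_min: float = SILHOUETTE_MIN,
    maf_min: float = MAF_MIN,
    apply_qc: bool = True,
    loci: list[DefinedLocus] | None = None,
) -> CopyNumberMatrix:
    """Full genotyping stage: depth matrix -> QC'd copy-number matrix.

    When ``loci`` is given (e.g. known locus spans), discovery is skipped and
    copy numbers are called at exactly those loci.
    """
    ncn_windows = normalize_depth(depth, gc_correct=gc_correct, gc_bins=gc_bins)
    if loci is None:
        loci = define_loci(
            ncn_windows, depth.windows,
            aberration_low=aberration_low, aberration_high=aberration_high,
            min_carrier_freq=min_carrier_freq, cn_max=cn_max,
        )
    n_ind = len(depth.individuals)
    ncn = np.empty((n_ind, len(loci)))
    for j, dl in enumerate(loci):
        ncn[:, j] = ncn_windows[:, list(dl.window_indices)].mean(axis=1)
    icn = call_integer_cn(ncn, cn_max=cn_max)
    out_loci = [
        CNVLocus(
            locus_id=dl.locus.locus_id, chrom=dl.locus.chrom,
            start=dl.locus.start, end=dl.locus.end,
            cnv_class=classify_cnv(icn[:, j]),
        )
        for j, dl in enumerate(loci)
    ]
    matrix = CopyNumberMatrix(
        loci=out_loci, individuals=list(depth.individuals), ncn=ncn, icn=icn
    )
    matrix.qc = [
        locus_qc(ncn[:, j], icn[:, j], silhouette_min, maf_min)
        for j in range(len(out_loci))
    ]
    if apply_qc:
        keep = [j for j, qc in enumerate(matrix.qc) if qc.passed]
        kept = matrix.subset_loci(keep)
        kept.qc = [matrix.qc[j] for j in keep]
        return kept
    return matrix


def loci_from_spans(
    depth: WindowDepthMatrix, spans: list[CNVLocus]
) -> list[DefinedLocus]:
    """Map known locus spans onto the depth matrix's window indices."""
    from bisect import bisect_left, bisect_right
    from collections import defaultdict

    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for i, w in enumerate(depth.windows):
        by_chrom[w.chrom].append((w.start, i))
    for lst in by_chrom.values():
        lst.sort()
    out = []
    for locus in spans:
        starts = by_chrom.get(locus.chrom, [])
        lo = bisect_left(starts, (locus.start, -1))
        hi = bisect_right(starts, (locus.end, len(depth.windows)))
        idx = [i for _, i in starts[lo:hi]]
        if not idx:
            raise ValidationError(f"no windows overlap locus {locus.locus_id}")
        out.append(DefinedLocus(locus=locus, window_indices=tuple(idx)))
    return out
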