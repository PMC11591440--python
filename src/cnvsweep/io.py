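"""Readers and writers for every external format the pipeline touches.

All text outputs are tab-separated UTF-8 with a single header line; headers
begin with ``#`` except the depth matrix, whose header is the bare column
names. Genomic coordinates are 1-based inclusive on disk and in memory; BED
(0-based half-open) is converted at the boundary.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CASE,
    CONTROL,
    CNVLocus,
    CnvClass,
    CopyNumberMatrix,
    GeneModel,
    GenomicWindow,
    LocusQC,
    ParseError,
    PathwayMap,
    PopulationDesign,
    ValidationError,
    WindowDepthMatrix,
    chrom_sort_key,
)

_DEPTH_META = ["chrom", "start", "end", "gc"]

SWEEP_COLUMNS = [
    "locus_id", "chrom", "start", "end", "vst", "fst",
    "rank_vst", "rank_fst", "candidate_vst", "candidate_fst", "candidate_both",
]


# ---------------------------------------------------------------- depth matrix

def write_depth_matrix(matrix: WindowDepthMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in matrix.windows],
            "start": [w.start for w in matrix.windows],
            "end": [w.end for w in matrix.windows],
            # repr guarantees a lossless float round trip
            "gc": [repr(w.gc) for w in matrix.windows],
        }
    )
    for i, ind in enumerate(matrix.individuals):
        df[ind] = matrix.depth[i]
    df.to_csv(path, sep="\t", index=False)


def _locate_bad_line(path, n_fields: int) -> str:
    """Scan for the first malformed data line, for error reporting."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                return f"line {lineno}: expected {n_fields} fields, found {len(parts)}"
            try:
                int(parts[1]); int(parts[2]); float(parts[3])
                for v in parts[4:]:
                    int(v)
            except ValueError:
                return f"line {lineno}: non-numeric value"
    return "unknown location"


def read_depth_matrix(path, window_size: int) -> WindowDepthMatrix:
    """Read a window-depth TSV (chrom, start, end, gc, one column per individual)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[: len(_DEPTH_META)] != _DEPTH_META:
        raise ParseError(f"{path}: line 1: header must start with {_DEPTH_META}")
    individuals = header[len(_DEPTH_META):]
    if not individuals:
        raise ParseError(f"{path}: line 1: no individual columns")
    try:
        df = pd.read_csv(
            path, sep="\t", float_precision="round_trip",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "gc": float,
                   **{ind: np.int64 for ind in individuals}},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {_locate_bad_line(path, len(header))}") from exc
    windows = [
        GenomicWindow(chrom=row.chrom, start=int(row.start), end=int(row.end), gc=float(row.gc))
        for row in df.itertuples(index=False)
    ]
    matrix = WindowDepthMatrix(
        windows=windows,
        individuals=list(individuals),
        depth=df[individuals].to_numpy(dtype=np.int64).T,
    )
    matrix.validate_window_size(window_size)
    return matrix


# ------------------------------------------------------------------- design

def write_design(design: PopulationDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#individual_id\tgroup\n")
        for ind, grp in zip(design.individuals, design.groups):
            fh.write(f"{ind}\t{grp}\n")


def read_design(path) -> PopulationDesign:
    inds, grps = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("#")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            if parts[1] not in (CASE, CONTROL):
                raise ParseError(f"{path}: line {lineno}: unknown group {parts[1]!r}")
            inds.append(parts[0])
            grps.append(parts[1])
    return PopulationDesign(tuple(inds), tuple(grps))


# -------------------------------------------------------------- gene models

def read_gene_models(path, dialect: str) -> list[GeneModel]:
    """Read gene intervals from GFF3 (gene features only) or BED.

    BED is 0-based half-open and converted to 1-based inclusive on read.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    if dialect == "bed":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}: line {lineno}: BED needs >= 3 fields")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
                if end0 <= start0:
                    raise ParseError(f"{path}: line {lineno}: empty or inverted interval")
                genes.append(GeneModel(gene_id=name, chrom=chrom, start=start0 + 1, end=end0, name=name))
    elif dialect == "gff3":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}: line {lineno}: GFF3 needs 9 fields")
                if parts[2] != "gene":
                    continue
                chrom, start, end = parts[0], int(parts[3]), int(parts[4])
                if end < start:
                    raise ParseError(f"{path}: line {lineno}: end < start")
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", f"{chrom}:{start}-{end}")
                if gid.startswith("gene:"):
                    gid = gid[5:]
                genes.append(GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                                       name=attrs.get("Name", gid)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'gff3' or 'bed'")
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start, g.end, g.gene_id))
    return genes


def write_gene_models(genes, path, dialect: str) -> None:
    if dialect == "bed":
        with open(path, "w", encoding="utf-8") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
    elif dialect == "gff3":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.gene_id};Name={g.name or g.gene_id}"
                fh.write(f"{g.chrom}\tcnvsweep\tgene\t{g.start}\t{g.end}\t.\t.\t.\t{attrs}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'gff3' or 'bed'")


# ---------------------------------------------------------------------- GMT

def read_gmt(path, background=None) -> PathwayMap:
    """Read gene sets in GMT format (name, description, member genes)."""
    pathways: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT needs name, description, genes")
            pid = parts[0]
            if pid in pathways:
                raise ParseError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = [g for g in parts[2:] if g]
    return PathwayMap(pathways, background=background)


def write_gmt(pathways: PathwayMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, genes in pathways.pathways.items():
            fh.write("\t".join([pid, pid] + sorted(genes)) + "\n")


# -------------------------------------------------------------- sweep table

def write_sweep_table(table: pd.DataFrame, path) -> None:
    """Write the per-locus sweep table (header line starts with ``#``)."""
    out = table.loc[:, SWEEP_COLUMNS].copy()
    out = out.rename(columns={"locus_id": "#locus_id"})
    out.to_csv(path, sep="\t", index=False)


def read_sweep_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"#locus_id": str, "chrom": str, "start": np.int64, "end": np.int64,
               "vst": float, "fst": float, "rank_vst": float, "rank_fst": float,
               "candidate_vst": bool, "candidate_fst": bool, "candidate_both": bool},
    )
    df = df.rename(columns={"#locus_id": "locus_id"})
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing sweep-table columns {missing}")
    return df


# ------------------------------------------------------- CNV genotype matrix

def _locus_frame(matrix: CopyNumberMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "#locus_id": [l.locus_id for l in matrix.loci],
            "chrom": [l.chrom for l in matrix.loci],
            "start": [l.start for l in matrix.loci],
            "end": [l.end for l in matrix.loci],
            "cnv_class": [l.cnv_class.value for l in matrix.loci],
        }
    )


def write_cnv_genotypes(matrix: CopyNumberMatrix, path) -> None:
    """Write integer copy numbers as a VCF-like TSV (one row per locus)."""
    df = _locus_frame(matrix)
    for i, ind in enumerate(matrix.individuals):
        df[ind] = matrix.icn[i]
    df.to_csv(path, sep="\t", index=False)


def write_normalized_cn(matrix: CopyNumberMatrix, path) -> None:
    """Companion table of continuous normalized copy numbers."""
    df = _locus_frame(matrix)
    for i, ind in enumerate(matrix.individuals):
        df[ind] = matrix.ncn[i]
    df.to_csv(path, sep="\t", index=False)


def read_copy_number_matrix(genotypes_path, ncn_path=None) -> CopyNumberMatrix:
    """Read a CopyNumberMatrix from the genotype TSV (+ optional ncn TSV).

    Without the companion file, the continuous matrix is the integer one.
    """
    gdf = pd.read_csv(genotypes_path, sep="\t", dtype={"#locus_id": str, "chrom": str})
    meta = ["#locus_id", "chrom", "start", "end", "cnv_class"]
    missing = [c for c in meta if c not in gdf.columns]
    if missing:
        raise ParseError(f"{genotypes_path}: missing columns {missing}")
    individuals = [c for c in gdf.columns if c not in meta]
    loci = [
        CNVLocus(
            locus_id=row[0], chrom=row[1], start=int(row[2]), end=int(row[3]),
            cnv_class=CnvClass(row[4]),
        )
        for row in gdf[meta].itertuples(index=False)
    ]
    icn = gdf[individuals].to_numpy(dtype=np.int64).T
    if ncn_path is not None:
        ndf = pd.read_csv(ncn_path, sep="\t", float_precision="round_trip", dtype={"#locus_id": str})
        if list(ndf["#locus_id"]) != [l.locus_id for l in loci]:
            raise ValidationError("normalized-CN table loci do not match genotype table")
        ncn = ndf[individuals].to_numpy(dtype=float).T
    else:
        ncn = icn.astype(float)
    return CopyNumberMatrix(loci=loci, individuals=individuals, ncn=ncn, icn=icn)


# ---------------------------------------------------------------- QC report

def write_qc_report(matrix: CopyNumberMatrix, path) -> None:
    if matrix.qc is None:
        raise ValidationError("matrix has no QC metrics")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#locus_id\tsilhouette\tmaf\tpassed\n")
        for locus, qc in zip(matrix.loci, matrix.qc):
            fh.write(f"{locus.locus_id}\t{qc.silhouette!r}\t{qc.maf!r}\t{qc.passed}\n")


def read_qc_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"#locus_id": str, "silhouette": float,
                                            "maf": float, "passed": bool})
    return df.rename(columns={"#locus_id": "locus_id"})


# --------------------------------------------------------------- enrichment

def write_enrichment(results: pd.DataFrame, path) -> None:
    out = results.rename(columns={"pathway_id": "#pathway_id"})
    out.to_csv(path, sep="\t", index=False)
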