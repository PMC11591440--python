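"""Domain types shared by every stage of the CNV sweep pipeline.

Coordinates are stored and reported 1-based inclusive throughout; BED
input/output converts at the boundary (see :mod:`cnvsweep.io`).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

CASE = "case"
CONTROL = "control"


class CnvSweepError(Exception):
    """Base class for package errors."""


class ParseError(CnvSweepError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CnvSweepError, ValueError):
    """Data violated a structural invariant."""


class ConfigError(CnvSweepError, ValueError):
    """A configuration value is out of range or inconsistent."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr2 before chr10, sex chromosomes last."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


class CnvClass(str, Enum):
    """Direction of a CNV locus relative to the diploid baseline CN=2."""

    DELETION = "deletion"
    DUPLICATION = "duplication"
    MIXED = "mixed"


def classify_cnv(icn: np.ndarray) -> CnvClass:
    """Classify a locus from its integer copy numbers.

    A locus is a deletion when every non-diploid copy number is below 2,
    a duplication when every one is above 2, and mixed when both kinds of
    carrier (or no carrier at all) are present.
    """
    icn = np.asarray(icn)
    low = bool((icn < 2).any())
    high = bool((icn > 2).any())
    if low and not high:
        return CnvClass.DELETION
    if high and not low:
        return CnvClass.DUPLICATION
    return CnvClass.MIXED


@dataclass(frozen=True)
class PopulationDesign:
    """Case/control labels for the cohort, in matrix column order."""

    individuals: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "individuals", tuple(self.individuals))
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.individuals) != len(self.groups):
            raise ValidationError("individuals and groups differ in length")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("individual identifiers are not unique")
        bad = sorted(set(self.groups) - {CASE, CONTROL})
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValidationError(
                "each group needs at least 2 individuals "
                f"(got {self.n_cases} cases, {self.n_controls} controls)"
            )

    @property
    def n_cases(self) -> int:
        return sum(g == CASE for g in self.groups)

    @property
    def n_controls(self) -> int:
        return sum(g == CONTROL for g in self.groups)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == CASE for g in self.groups], dtype=bool)

    def reorder(self, individuals: Sequence[str]) -> "PopulationDesign":
        """Return the design restricted/reordered to ``individuals``."""
        lookup = dict(zip(self.individuals, self.groups))
        missing = [i for i in individuals if i not in lookup]
        if missing:
            raise ValidationError(f"individuals absent from design: {missing}")
        return PopulationDesign(tuple(individuals), tuple(lookup[i] for i in individuals))


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed-width genomic window with its GC fraction."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    gc: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"window end < start: {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError(f"GC fraction outside [0,1]: {self.gc}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


_SEX_CHROMS = {"x", "y", "chrx", "chry"}


def is_autosome(chrom: str) -> bool:
    return chrom.lower() not in _SEX_CHROMS


@dataclass
class WindowDepthMatrix:
    """Per-individual read-depth counts over fixed-width windows."""

    windows: list[GenomicWindow]
    individuals: list[str]
    depth: np.ndarray  # shape (n_individuals, n_windows), non-negative ints

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if self.depth.shape != (len(self.individuals), len(self.windows)):
            raise ValidationError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.windows)} windows"
            )
        if not np.issubdtype(self.depth.dtype, np.integer):
            if np.any(self.depth != np.floor(self.depth)) or np.any(~np.isfinite(self.depth)):
                raise ValidationError("depth entries must be integers")
            self.depth = self.depth.astype(np.int64)
        if (self.depth < 0).any():
            raise ValidationError("depth entries must be non-negative")
        keys = [(chrom_sort_key(w.chrom), w.start) for w in self.windows]
        if keys != sorted(keys):
            raise ValidationError("windows are not sorted by (chrom, start)")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def validate_window_size(self, window_size: int) -> None:
        for idx, w in enumerate(self.windows):
            if w.width != window_size:
                raise ValidationError(
                    f"window {idx} ({w.chrom}:{w.start}-{w.end}) has width "
                    f"{w.width}, expected {window_size}"
                )

    def autosomal_mask(self) -> np.ndarray:
        return np.array([is_autosome(w.chrom) for w in self.windows], dtype=bool)

    def __eq__(self, other):
        return (
            isinstance(other, WindowDepthMatrix)
            and self.windows == other.windows
            and self.individuals == other.individuals
            and np.array_equal(self.depth, other.depth)
        )


@dataclass(frozen=True)
class CNVLocus:
    """A CNV locus (merged run of aberrant windows), 1-based inclusive."""

    locus_id: str
    chrom: str
    start: int
    end: int
    cnv_class: CnvClass

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"locus end < start: {self.locus_id}")


@dataclass(frozen=True)
class LocusQC:
    """Per-locus genotyping quality: silhouette, minor-class frequency."""

    silhouette: float
    maf: float
    passed: bool

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.silhouette <= 1.0 + 1e-12:
            raise ValidationError(f"silhouette outside [-1,1]: {self.silhouette}")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValidationError(f"MAF outside [0,0.5]: {self.maf}")


@dataclass
class CopyNumberMatrix:
    """Normalized (continuous) and integer copy numbers over CNV loci."""

    loci: list[CNVLocus]
    individuals: list[str]
    ncn: np.ndarray  # (n_individuals, n_loci), float, >= 0
    icn: np.ndarray  # (n_individuals, n_loci), int
    qc: list[LocusQC] | None = None

    def __post_init__(self):
        self.ncn = np.asarray(self.ncn, dtype=float)
        self.icn = np.asarray(self.icn)
        shape = (len(self.individuals), len(self.loci))
        if self.ncn.shape != shape or self.icn.shape != shape:
            raise ValidationError(
                f"matrix shapes {self.ncn.shape}/{self.icn.shape} do not match {shape}"
            )
        if (self.ncn < 0).any():
            raise ValidationError("normalized copy numbers must be >= 0")
        if not np.issubdtype(self.icn.dtype, np.integer):
            if np.any(self.icn != np.floor(self.icn)):
                raise ValidationError("integer copy numbers must be integers")
            self.icn = self.icn.astype(np.int64)
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("locus_id values are not unique")
        if self.qc is not None and len(self.qc) != len(self.loci):
            raise ValidationError("qc length does not match loci")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, indices: Sequence[int]) -> "CopyNumberMatrix":
        indices = list(indices)
        return CopyNumberMatrix(
            loci=[self.loci[i] for i in indices],
            individuals=list(self.individuals),
            ncn=self.ncn[:, indices].copy(),
            icn=self.icn[:, indices].copy(),
            qc=None if self.qc is None else [self.qc[i] for i in indices],
        )

    def __eq__(self, other):
        return (
            isinstance(other, CopyNumberMatrix)
            and self.loci == other.loci
            and self.individuals == other.individuals
            and np.allclose(self.ncn, other.ncn)
            and np.array_equal(self.icn, other.icn)
            and self.qc == other.qc
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"gene end < start: {self.gene_id}")


@dataclass
class PathwayMap:
    """Pathway/gene-set membership against a background gene universe.

    Pathway gene sets are intersected with the background on construction,
    so every tested set is a subset of the universe.
    """

    pathways: dict[str, frozenset[str]]
    background: frozenset[str]

    def __init__(self, pathways: Mapping[str, Iterable[str]], background: Iterable[str] | None = None):
        raw = {pid: frozenset(genes) for pid, genes in pathways.items()}
        if background is None:
            bg: set[str] = set()
            for genes in raw.values():
                bg |= genes
            self.background = frozenset(bg)
        else:
            self.background = frozenset(background)
        self.pathways = {pid: genes & self.background for pid, genes in raw.items()}

    def __len__(self) -> int:
        return len(self.pathways)
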