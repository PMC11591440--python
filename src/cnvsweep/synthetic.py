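"""Synthetic case/control CNV cohorts with planted group differentiation.

The generator emulates the study design this package targets: a cohort of
37 diploid individuals (23 cases carrying the trait, 14 controls) genotyped
at ~12,310 CNV loci built from 800 bp read-depth windows, with a configurable
fraction of loci whose copy-number distribution differs between groups.

Two stages mirror the real data flow:

* :func:`simulate_cohort` draws truth integer copy numbers per individual and
  locus (the quantity a perfect genotyper would recover), together with the
  population design and a truth table flagging the planted loci.
* :func:`simulate_depth` converts truth copy numbers into windowed read
  depths under a Poisson sequencing model, the input to the genotyper.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CASE,
    CONTROL,
    CNVLocus,
    CopyNumberMatrix,
    ConfigError,
    GenomicWindow,
    PopulationDesign,
    WindowDepthMatrix,
    classify_cnv,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated cohort.

    The defaults reproduce the target study's conditions: 23 cases vs 14
    controls, 12,310 CNV loci on 800 bp windows, 1% of loci differentiated
    with a copy-number offset of |2| in the case group, and a mean sequencing
    depth of 30 reads per diploid window. Loci span ``windows_per_locus``
    adjacent windows (CNV regions are multi-window in real data) and are
    separated by ``locus_gap_windows`` unsequenced windows so merged runs of
    aberrant windows correspond one-to-one to simulated loci.
    """

    n_cases: int = 23
    n_controls: int = 14
    n_loci: int = 12310
    windows_per_locus: int = 4
    window_size: int = 800
    mean_depth: float = 30.0
    frac_differentiated: float = 0.01
    effect: int = 2
    effect_sign: str = "random"  # "random" | "positive" | "negative"
    cn_max: int = 8
    gc_bias_amplitude: float = 0.0
    minor_freq: float = 0.2
    min_carriers: int = 2
    overdispersion: float = 1.0
    depth_factor_range: tuple[float, float] = (0.8, 1.2)
    n_chroms: int = 29
    locus_gap_windows: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_loci", "windows_per_locus",
                     "window_size", "cn_max", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigError("each group needs at least 2 individuals")
        if not 0.0 <= self.frac_differentiated <= 1.0:
            raise ConfigError("frac_differentiated must be in [0,1]")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if not 0.0 < self.minor_freq < 1.0:
            raise ConfigError("minor_freq must be in (0,1)")
        if self.effect_sign not in ("random", "positive", "negative"):
            raise ConfigError(f"unknown effect_sign {self.effect_sign!r}")
        if self.overdispersion < 1.0:
            raise ConfigError("overdispersion must be >= 1")
        if self.min_carriers > self.n_individuals:
            raise ConfigError("min_carriers exceeds cohort size")
        signs = {"random": (1, -1), "positive": (1,), "negative": (-1,)}[self.effect_sign]
        for s in signs:
            shifted = 2 + s * self.effect
            if not 0 <= shifted <= self.cn_max:
                raise ConfigError(
                    f"effect {s * self.effect:+d} shifts the modal CN 2 to "
                    f"{shifted}, outside [0, {self.cn_max}]"
                )

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_planted(self) -> int:
        return round(self.frac_differentiated * self.n_loci)


def _design(config: SimulationConfig) -> PopulationDesign:
    inds = [f"case{i + 1:03d}" for i in range(config.n_cases)] + [
        f"ctrl{i + 1:03d}" for i in range(config.n_controls)
    ]
    groups = [CASE] * config.n_cases + [CONTROL] * config.n_controls
    return PopulationDesign(tuple(inds), tuple(groups))


def _locus_layout(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """(chrom, start, end) per locus, contiguous blocks per chromosome."""
    per_chrom = math.ceil(config.n_loci / config.n_chroms)
    width = config.windows_per_locus * config.window_size
    stride = width + config.locus_gap_windows * config.window_size
    layout = []
    for i in range(config.n_loci):
        chrom = f"chr{i // per_chrom + 1}"
        pos = i % per_chrom
        start = 1 + pos * stride
        layout.append((chrom, start, start + width - 1))
    return layout


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CopyNumberMatrix, PopulationDesign, pd.DataFrame]:
    """Draw truth copy numbers for the configured cohort.

    At non-planted loci every individual draws from the same baseline
    distribution: modal CN 2, with a per-locus minor class (CN 1 or CN 3,
    equally likely) carried at frequency ``minor_freq``. Loci are redrawn
    until at least ``min_carriers`` carriers exist, because CNV loci are by
    construction ascertained polymorphic variants. At planted loci the case
    group's copy numbers are additionally shifted by ``effect`` (sign per
    ``effect_sign``), clipped to [0, cn_max].

    Returns the truth copy-number matrix (ncn equals icn exactly), the
    population design, and a truth table with one row per locus
    (locus_id, chrom, start, end, planted, effect, minor_cn,
    mean_cn_case, mean_cn_control).
    """
    rng = np.random.default_rng([config.seed, 0])
    design = _design(config)
    n_ind, n_loci = config.n_individuals, config.n_loci
    case_mask = design.case_mask

    layout = _locus_layout(config)
    planted_idx = np.sort(rng.choice(n_loci, size=config.n_planted, replace=False))
    planted = np.zeros(n_loci, dtype=bool)
    planted[planted_idx] = True

    minor_cn = rng.choice([1, 3], size=n_loci)
    if config.effect_sign == "random":
        signs = rng.choice([-1, 1], size=n_loci)
    else:
        signs = np.full(n_loci, 1 if config.effect_sign == "positive" else -1)

    carrier = rng.random((n_loci, n_ind)) < config.minor_freq
    # ascertainment: CNV loci are polymorphic by definition
    deficient = np.flatnonzero(carrier.sum(axis=1) < config.min_carriers)
    while deficient.size:
        carrier[deficient] = rng.random((deficient.size, n_ind)) < config.minor_freq
        deficient = deficient[carrier[deficient].sum(axis=1) < config.min_carriers]

    icn = np.where(carrier, minor_cn[:, None], 2).astype(np.int64)
    shift = np.where(planted, signs * config.effect, 0)
    shifted_cells = planted[:, None] & case_mask[None, :]
    icn = np.where(shifted_cells, np.clip(icn + shift[:, None], 0, config.cn_max), icn)

    loci = []
    for i, (chrom, start, end) in enumerate(layout):
        loci.append(
            CNVLocus(
                locus_id=f"{chrom}:{start}-{end}",
                chrom=chrom,
                start=start,
                end=end,
                cnv_class=classify_cnv(icn[i]),
            )
        )

    matrix = CopyNumberMatrix(
        loci=loci,
        individuals=list(design.individuals),
        ncn=icn.T.astype(float),
        icn=icn.T,
    )
    truth = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "planted": planted,
            "effect": shift,
            "minor_cn": minor_cn,
            "mean_cn_case": icn[:, case_mask].mean(axis=1),
            "mean_cn_control": icn[:, ~case_mask].mean(axis=1),
        }
    )
    return matrix, design, truth


def gc_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Sinusoidal GC coverage bias, 1 + A*sin(2*pi*gc), floored at 0.05."""
    return np.maximum(1.0 + amplitude * np.sin(2.0 * np.pi * np.asarray(gc)), 0.05)


def simulate_depth(truth: CopyNumberMatrix, config: SimulationConfig) -> WindowDepthMatrix:
    """Draw windowed read depths from the truth copy numbers.

    Each locus expands into ``windows_per_locus`` adjacent windows that share
    the locus copy number. Depth at window w of individual i is
    Poisson(f_i * lambda * CN_iw/2 * g(GC_w)) where f_i is a per-individual
    library-size factor (uniform on ``depth_factor_range``) and g is the
    optional sinusoidal GC bias. With ``overdispersion`` m > 1 the Poisson
    mean is itself Gamma-distributed with shape lambda_iw/(m-1), giving a
    negative-binomial marginal with variance m times the mean.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_ind = len(truth.individuals)
    wpl = config.windows_per_locus

    windows: list[GenomicWindow] = []
    gcs = rng.uniform(0.3, 0.7, size=truth.n_loci * wpl)
    for j, locus in enumerate(truth.loci):
        for k in range(wpl):
            start = locus.start + k * config.window_size
            windows.append(
                GenomicWindow(
                    chrom=locus.chrom,
                    start=start,
                    end=start + config.window_size - 1,
                    gc=float(gcs[j * wpl + k]),
                )
            )

    factors = rng.uniform(*config.depth_factor_range, size=n_ind)
    cn = np.repeat(truth.icn, wpl, axis=1)  # (n_ind, n_windows)
    g = gc_factor(gcs, config.gc_bias_amplitude)[None, :]
    lam = factors[:, None] * config.mean_depth * (cn / 2.0) * g
    if config.overdispersion > 1.0:
        shape = lam / (config.overdispersion - 1.0)
        with np.errstate(invalid="ignore"):
            lam = np.where(lam > 0, rng.gamma(np.maximum(shape, 1e-12)) * (config.overdispersion - 1.0), 0.0)
    depth = rng.poisson(lam)
    return WindowDepthMatrix(windows=windows, individuals=list(truth.individuals), depth=depth)


def write_truth_table(truth: pd.DataFrame, path) -> None:
    out = truth.rename(columns={"locus_id": "#locus_id"})
    out.to_csv(path, sep="\t", index=False)
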