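"""Shared fixtures: one full-size simulated cohort reused across the suite."""
from __future__ import annotations

import numpy as np
import pytest

from cnvsweep.genotyper import genotype_cohort, loci_from_spans
from cnvsweep.synthetic import SimulationConfig, simulate_cohort, simulate_depth

#: fixed seed for all full-size study fixtures
SEED = 7


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """The study-design defaults: 23 cases / 14 controls, 12,310 loci."""
    return SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    """(truth CopyNumberMatrix, PopulationDesign, truth table)."""
    return simulate_cohort(study_config)


@pytest.fixture(scope="session")
def study_depth(study_config, study_cohort):
    truth_matrix, _, _ = study_cohort
    return simulate_depth(truth_matrix, study_config)


@pytest.fixture(scope="session")
def genotyped_at_truth_loci(study_config, study_cohort, study_depth):
    """Copy numbers re-called from simulated depth at the true locus spans."""
    truth_matrix, _, _ = study_cohort
    loci = loci_from_spans(study_depth, truth_matrix.loci)
    return genotype_cohort(study_depth, loci=loci, apply_qc=False)


@pytest.fixture()
def small_config() -> SimulationConfig:
    """A light cohort for fast unit tests (37 individuals x 250 loci)."""
    return SimulationConfig(n_loci=250, seed=11)
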