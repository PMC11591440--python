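"""V_ST, Weir-Cockerham F_ST, top-quantile selection and intersection."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvsweep.model import CnvClass, PopulationDesign, ValidationError
from cnvsweep.sweep import (
    POPULATION,
    SAMPLE,
    SweepConfig,
    build_sweep_table,
    cn_to_biallelic,
    fst_for_locus,
    fst_wc,
    intersect_candidates,
    top_quantile,
    vst,
)


def _design(n1: int, n2: int) -> PopulationDesign:
    return PopulationDesign(
        tuple(f"a{i}" for i in range(n1)) + tuple(f"b{i}" for i in range(n2)),
        ("case",) * n1 + ("control",) * n2,
    )


# ------------------------------------------------------------------- V_ST

class TestVst:
    def test_zero_within_group_variance_gives_one(self):
        res = vst([4, 4, 4, 2, 2, 2], _design(3, 3))
        assert res.v_within == 0.0
        assert res.vst == 1.0

    def test_identical_groups_give_zero_under_population_convention(self):
        res = vst([1, 2, 3, 1, 2, 3], _design(3, 3), convention=POPULATION)
        assert res.vst == pytest.approx(0.0, abs=1e-15)
        # under the sample convention V_S exceeds V_T for identical groups
        assert vst([1, 2, 3, 1, 2, 3], _design(3, 3), convention=SAMPLE).vst <= 0.0

    def test_derived_example_sample_two_sevenths(self):
        """g1=(2,3,4), g2=(2,2,2): V_1=1, V_S=0.5, V_T=0.7, vst=2/7."""
        res = vst([2, 3, 4, 2, 2, 2], _design(3, 3), convention=SAMPLE)
        assert res.v_total == pytest.approx(0.7)
        assert res.v_within == pytest.approx(0.5)
        assert res.vst == pytest.approx(2 / 7)
        # the population convention disagrees on the same data (documented)
        pop = vst([2, 3, 4, 2, 2, 2], _design(3, 3), convention=POPULATION)
        assert pop.vst == pytest.approx(3 / 7)

    def test_undefined_when_total_variance_zero(self):
        res = vst([2, 2, 2, 2], _design(2, 2))
        assert not res.defined and math.isnan(res.vst)

    def test_group_smaller_than_two_is_an_error(self):
        # the design type refuses degenerate groups at construction...
        with pytest.raises(ValidationError):
            PopulationDesign(("a", "b", "c"), ("case", "case", "control"))
        # ...and vst refuses values that do not match the design
        with pytest.raises(ValidationError):
            vst([1, 2, 3], _design(2, 2), SAMPLE)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(-50, 50).map(lambda v: round(v, 2)), min_size=4, max_size=12),
        n1=st.integers(2, 6),
        shift=st.floats(-100, 100),
        scale=st.floats(-10, 10).filter(lambda x: abs(x) > 0.1),
        convention=st.sampled_from([SAMPLE, POPULATION]),
    )
    def test_shift_and_scale_invariance(self, vals, n1, shift, scale, convention):
        """V_ST is unchanged by affine transforms v -> scale*v + shift."""
        if len(vals) - n1 < 2:
            n1 = len(vals) - 2
        design = _design(n1, len(vals) - n1)
        base = vst(vals, design, convention)
        trans = vst([scale * v + shift for v in vals], design, convention)
        assert base.defined == trans.defined
        if base.defined:
            assert trans.vst == pytest.approx(base.vst, rel=1e-5, abs=1e-7)

    def test_conventions_agree_on_ranking_for_equal_group_sizes(self):
        """With n1 = n2 the two conventions order loci identically."""
        rng = np.random.default_rng(3)
        design = _design(8, 8)
        loci = rng.normal(2, 1, size=(40, 16))
        s = [vst(row, design, SAMPLE).vst for row in loci]
        p = [vst(row, design, POPULATION).vst for row in loci]
        assert list(np.argsort(s)) == list(np.argsort(p))


# ------------------------------------------------------------------- F_ST

def wc_oracle(g1, g2):
    """Literal transcription of the Weir & Cockerham (1984) two-population
    estimator from genotype codes, written independently of the package."""
    g1, g2 = list(g1), list(g2)
    r = 2
    n1, n2 = len(g1), len(g2)
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return a, b, c, None
    return a, b, c, a / (a + b + c)


class TestFst:
    def test_fixed_difference_theta_one(self):
        codes = [2, 2, 2, 0, 0, 0]
        res = fst_wc(codes, _design(3, 3))
        assert res.theta == pytest.approx(1.0, abs=1e-12)

    def test_identical_polymorphic_groups_match_oracle_near_zero(self):
        codes = [0, 1, 2, 0, 1, 2]
        res = fst_wc(codes, _design(3, 3))
        *_, theta = wc_oracle(codes[:3], codes[3:])
        assert res.theta == pytest.approx(theta, abs=1e-12)
        assert abs(res.theta) < 0.35  # no differentiation signal

    def test_three_vs_three_example_matches_oracle(self):
        g1, g2 = [0, 1, 2], [0, 0, 1]
        res = fst_wc(g1 + g2, _design(3, 3))
        a, b, c, theta = wc_oracle(g1, g2)
        assert (res.a, res.b, res.c) == pytest.approx((a, b, c), abs=1e-12)
        assert res.theta == pytest.approx(theta, abs=1e-12)

    def test_monomorphic_locus_is_flagged_undefined(self):
        res = fst_wc([0, 0, 0, 0], _design(2, 2))
        assert not res.defined and math.isnan(res.theta)

    def test_matches_literal_oracle_on_random_loci(self):
        """200 random small loci agree with the transcription to 1e-12."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            n1, n2 = rng.integers(2, 10), rng.integers(2, 10)
            g1 = rng.integers(0, 3, n1).tolist()
            g2 = rng.integers(0, 3, n2).tolist()
            a, b, c, theta = wc_oracle(g1, g2)
            if theta is None:
                continue
            res = fst_wc(g1 + g2, _design(n1, n2))
            assert res.theta == pytest.approx(theta, abs=1e-12)
            checked += 1

    def test_invalid_genotype_codes_rejected(self):
        with pytest.raises(ValidationError):
            fst_wc([0, 3, 1, 2], _design(2, 2))


class TestBiallelicEncoding:
    def test_deletion_mapping(self):
        (codes,) = cn_to_biallelic([2, 1, 0], CnvClass.DELETION)
        assert codes.tolist() == [0, 1, 2]

    def test_duplication_mapping_saturates_at_cn4(self):
        (codes,) = cn_to_biallelic([2, 3, 6], CnvClass.DUPLICATION)
        assert codes.tolist() == [0, 1, 2]

    def test_class_inconsistency_is_an_error(self):
        with pytest.raises(ValidationError):
            cn_to_biallelic([2, 1, 3], CnvClass.DELETION)
        with pytest.raises(ValidationError):
            cn_to_biallelic([2, 1, 3], CnvClass.DUPLICATION)

    def test_mixed_locus_scores_both_sublocus_thetas_and_keeps_max(self):
        icn = [1, 1, 2, 2, 3, 3, 2, 2]
        design = _design(4, 4)
        del_codes, dup_codes = cn_to_biallelic(icn, CnvClass.MIXED)
        assert del_codes.tolist() == [1, 1, 0, 0, 0, 0, 0, 0]
        assert dup_codes.tolist() == [0, 0, 0, 0, 1, 1, 0, 0]
        *_, theta_del = wc_oracle(del_codes[:4].tolist(), del_codes[4:].tolist())
        *_, theta_dup = wc_oracle(dup_codes[:4].tolist(), dup_codes[4:].tolist())
        res = fst_for_locus(icn, CnvClass.MIXED, design)
        assert res.theta == pytest.approx(max(theta_del, theta_dup), abs=1e-12)


# -------------------------------------------------------------- selection

class TestTopQuantile:
    def test_study_scale_universe_selects_123(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.random(12310), index=[f"L{i}" for i in range(12310)])
        selected, threshold = top_quantile(scores, alpha=0.01)
        assert len(selected) == 123
        assert threshold == min(scores[s] for s in selected)

    def test_one_percent_of_hundred_selects_the_max(self):
        scores = pd.Series(np.arange(100, dtype=float), index=[f"L{i}" for i in range(100)])
        selected, threshold = top_quantile(scores, alpha=0.01)
        assert selected == ["L99"] and threshold == 99.0

    def test_boundary_ties_resolved_by_locus_order(self):
        # N=10, alpha=0.25 -> k=2; three loci tied at the boundary value 5
        scores = pd.Series(
            [9.0, 5.0, 5.0, 5.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1],
            index=[f"L{i}" for i in range(10)],
        )
        selected, threshold = top_quantile(scores, alpha=0.25)
        assert selected == ["L0", "L1"]  # earliest tied locus wins
        assert threshold == 5.0

    def test_undefined_scores_excluded_from_universe(self):
        scores = pd.Series([np.nan] * 50 + list(np.arange(100.0)),
                           index=[f"L{i}" for i in range(150)])
        selected, _ = top_quantile(scores, alpha=0.01)
        assert len(selected) == 1  # floor(0.01 * 100), not 0.01 * 150

    def test_invalid_alpha_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        for alpha in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                top_quantile(scores, alpha=alpha)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 400),
        alpha=st.floats(0.005, 0.5),
        seed=st.integers(0, 2**16),
    )
    def test_selection_size_is_floor_alpha_n(self, n, alpha, seed):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=n), index=[f"L{i}" for i in range(n)])
        selected, _ = top_quantile(scores, alpha=alpha)
        assert len(selected) == max(1, math.floor(alpha * n))


class TestIntersection:
    def test_disjoint_sets_empty(self):
        assert intersect_candidates(["a", "b"], ["c", "d"]) == []

    def test_identical_sets_preserved(self):
        ids = [f"L{i}" for i in range(123)]
        assert intersect_candidates(ids, list(reversed(ids))) == ids

    def test_matches_brute_force_on_random_subsets(self):
        rng = np.random.default_rng(77)
        universe = [f"L{i}" for i in range(500)]
        a = [u for u in universe if rng.random() < 0.3]
        b = [u for u in universe if rng.random() < 0.3]
        expected = [u for u in a if u in set(b)]
        assert intersect_candidates(a, b) == expected


class TestSweepTable:
    def test_table_consistent_with_scalar_statistics(self, small_config):
        from cnvsweep.synthetic import simulate_cohort

        matrix, design, _ = simulate_cohort(small_config)
        table, summary = build_sweep_table(matrix, design)
        # spot-check 20 loci against the scalar code paths
        rng = np.random.default_rng(1)
        for j in rng.choice(matrix.n_loci, 20, replace=False):
            v = vst(matrix.ncn[:, j], design)
            f = fst_for_locus(matrix.icn[:, j], matrix.loci[j].cnv_class, design)
            row = table.iloc[j]
            if v.defined:
                assert row["vst"] == pytest.approx(v.vst, abs=1e-12)
            else:
                assert math.isnan(row["vst"])
            if f.defined:
                assert row["fst"] == pytest.approx(f.theta, abs=1e-12)
            else:
                assert math.isnan(row["fst"])
        assert summary["k_vst"] == max(1, math.floor(0.01 * summary["n_ranked_vst"]))

    def test_negative_scores_are_not_clamped(self, small_config):
        from cnvsweep.synthetic import simulate_cohort

        matrix, design, _ = simulate_cohort(small_config)
        table, _ = build_sweep_table(matrix, design)
        assert (table["fst"].dropna() < 0).any() or (table["vst"].dropna() < 0).any()
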