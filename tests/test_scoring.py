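"""Per-scaffold and assembly-level score computation."""

import math

import numpy as np
import pytest

from asmqual.align_filter import FilteredChain, resolve_residual_overlaps
from asmqual.genome_io import AlignmentRecord, SequenceEntry
from asmqual.scoring import (
    ScaffoldScore,
    assembly_quality,
    coverage_curve_area,
    inverted_redundancy,
    length_scaling,
    penalty,
    quality_curve_area,
    reward,
    scaffold_quality,
    score_assembly,
)


def chain_for(qid, qlen, aligned_bp, ref_intervals=None):
    alns = []
    if ref_intervals:
        pos = 0
        for ref, rs, re_ in ref_intervals:
            span = re_ - rs
            alns.append(
                AlignmentRecord(qid, qlen, pos, pos + span, "+", ref, 10_000_000, rs, re_, span, span)
            )
            pos += span
    chain = FilteredChain(query_id=qid, query_len=qlen, alignments=alns)
    if alns:
        return resolve_residual_overlaps(chain)
    chain.total_aligned_query_bp = aligned_bp
    return chain


def make_score(qid, l_s, quality, aligned_ref_bp=0):
    return ScaffoldScore(
        query_id=qid, l_s=l_s, reward=1.0, penalty=0.0, length_scaling=1.0,
        quality=quality, aligned_ref_bp=aligned_ref_bp,
    )


class TestReward:
    def test_full_nongap_alignment(self):
        scf = SequenceEntry("s", 1000, [(0, 100)], None)
        assert reward(scf, chain_for("s", 1000, 900)) == 1.0

    def test_partial(self):
        scf = SequenceEntry("s", 1000, [], None)
        assert reward(scf, chain_for("s", 1000, 450)) == pytest.approx(0.45)

    def test_empty_chain(self):
        scf = SequenceEntry("s", 1000, [], None)
        assert reward(scf, chain_for("s", 1000, 0)) == 0.0

    def test_all_gap_warns_zero(self):
        scf = SequenceEntry("s", 100, [(0, 100)], None)
        with pytest.warns(UserWarning):
            assert reward(scf, chain_for("s", 100, 0)) == 0.0


class TestPenalty:
    @pytest.mark.parametrize("m,eps,expected", [
        (0, 0.0, 0.0),
        (1, 0.0, 0.0),          # excess of exactly 1: no penalty
        (5, 4.5, 0.0),
        (100, 0.0, 1.0),        # log100(100)
        (10, 0.0, 0.5),         # log100(10)
        (10_000, 0.0, 2.0),
    ])
    def test_values(self, m, eps, expected):
        assert penalty(m, eps) == pytest.approx(expected)

    def test_artifact_credit_reduces_penalty(self):
        assert penalty(100, 90.0) == pytest.approx(0.5)


class TestLengthScaling:
    def test_at_or_above_theta(self):
        assert length_scaling(500, 500) == 1.0
        assert length_scaling(5000, 500) == 1.0

    def test_tenth(self):
        assert length_scaling(50_000, 500_000) == pytest.approx(0.5)

    def test_hundredth(self):
        assert length_scaling(5_000, 500_000) == pytest.approx(1 / 3)

    def test_monotone_increasing_below_theta(self):
        vals = [length_scaling(l, 1_000_000) for l in (100, 10_000, 500_000, 999_999)]
        assert vals == sorted(vals) and all(0 < v < 1 for v in vals)


@pytest.mark.parametrize("r,p,L,expected", [
    (1.0, 0.0, 1.0, 1.0),
    (1.0, 1.0, 1.0, 0.5),
    (0.8, 0.0, 0.5, 0.4),
])
def test_scaffold_quality(r, p, L, expected):
    assert scaffold_quality(r, p, L) == pytest.approx(expected)


class TestQualityCurve:
    def test_all_perfect(self):
        delta, curve = quality_curve_area([make_score("a", 100, 1.0), make_score("b", 50, 1.0)])
        assert delta == pytest.approx(1.0, abs=1e-12)
        assert all(v == 1.0 for _, v in curve)

    def test_all_zero(self):
        delta, curve = quality_curve_area([make_score("a", 100, 0.0)])
        assert delta == pytest.approx(0.005)
        assert curve[0][1] == 1.0 and curve[1][1] == 0.0

    def test_two_scaffold_hand_value(self):
        scores = [make_score("a", 100, 1.0), make_score("b", 300, 0.5)]
        delta, _ = quality_curve_area(scores)
        assert delta == pytest.approx(0.62875)

    def test_curve_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        scores = [make_score(f"s{i}", int(rng.integers(1, 1000)), float(rng.random())) for i in range(30)]
        _, curve = quality_curve_area(scores)
        vals = [v for _, v in curve]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_area_matches_trapezoid_of_curve(self):
        rng = np.random.default_rng(1)
        scores = [make_score(f"s{i}", int(rng.integers(1, 1000)), float(rng.random())) for i in range(10)]
        delta, curve = quality_curve_area(scores)
        grid, vals = zip(*curve)
        assert delta == pytest.approx(np.trapezoid(vals, grid), abs=1e-15)


class TestCoverageCurve:
    def _reference(self):
        return [SequenceEntry("chr1", 1000, [], None), SequenceEntry("chr2", 1000, [], None)]

    def test_perfect_tiling(self):
        ref = self._reference()
        chains = {
            "a": chain_for("a", 1000, 1000, [("chr1", 0, 1000)]),
            "b": chain_for("b", 1000, 1000, [("chr2", 0, 1000)]),
        }
        scores = [make_score("a", 1000, 1.0, 1000), make_score("b", 1000, 1.0, 1000)]
        omega, curve, phi = coverage_curve_area(scores, chains, ref)
        assert omega == pytest.approx(1.0, abs=1e-12)
        assert phi == 2000

    def test_no_alignments(self):
        ref = self._reference()
        omega, _, phi = coverage_curve_area(
            [make_score("a", 100, 0.0)], {"a": chain_for("a", 100, 0)}, ref
        )
        # the empty union contributes 0 at every threshold
        assert omega == 0.0 and phi == 0

    def test_half_covered_constant_curve(self):
        ref = self._reference()
        chains = {"a": chain_for("a", 1000, 1000, [("chr1", 0, 1000)])}
        scores = [make_score("a", 1000, 1.0, 1000)]
        omega, curve, phi = coverage_curve_area(scores, chains, ref)
        assert omega == pytest.approx(0.5, abs=1e-12)
        assert all(v == 0.5 for _, v in curve)

    def test_cross_scaffold_overlap_counted_once_in_phi(self):
        ref = self._reference()
        chains = {
            "a": chain_for("a", 100, 100, [("chr1", 0, 100)]),
            "b": chain_for("b", 100, 100, [("chr1", 50, 150)]),
        }
        scores = [make_score("a", 100, 1.0, 100), make_score("b", 100, 1.0, 100)]
        _, _, phi = coverage_curve_area(scores, chains, ref)
        assert phi == 150


class TestInvertedRedundancy:
    def test_disjoint_is_one(self):
        scores = [make_score("a", 100, 1.0, 100), make_score("b", 100, 1.0, 100)]
        assert inverted_redundancy(scores, phi=200) == 1.0

    def test_partial_overlap(self):
        scores = [make_score("a", 100, 1.0, 100), make_score("b", 100, 1.0, 100)]
        assert inverted_redundancy(scores, phi=150) == pytest.approx(0.75)

    def test_k_fold_duplication(self):
        k = 4
        scores = [make_score(f"s{i}", 100, 1.0, 100) for i in range(k)]
        assert inverted_redundancy(scores, phi=100) == pytest.approx(1 / k)

    def test_nothing_aligned_raises(self):
        with pytest.raises(ZeroDivisionError):
            inverted_redundancy([make_score("a", 100, 0.0, 0)], phi=0)


class TestAssemblyQuality:
    @pytest.mark.parametrize("d,o,p,expected", [
        (1.0, 1.0, 1.0, 1.0),
        (0.512, 1.0, 1.0, 0.8),
        (0.0, 0.9, 0.9, 0.0),
    ])
    def test_geometric_mean(self, d, o, p, expected):
        assert assembly_quality(d, o, p) == pytest.approx(expected)

    def test_no_alignment_falls_back_to_zero(self):
        ref = [SequenceEntry("chr1", 1000, [], None)]
        scores = [make_score("a", 100, 0.0, 0)]
        chains = {"a": chain_for("a", 100, 0)}
        with pytest.warns(UserWarning, match="no aligned"):
            result = score_assembly(scores, chains, ref)
        assert result.quality == 0.0 and result.pi == 0.0

    def test_invariant_under_reordering_and_renaming(self):
        ref = [SequenceEntry("chr1", 1000, [], None)]
        def build(names, order):
            scores, chains = [], {}
            spec = [(300, 1.0, ("chr1", 0, 300)), (200, 0.6, ("chr1", 500, 700))]
            for name, idx in zip(names, order):
                l, q, iv = spec[idx]
                scores.append(make_score(name, l, q, iv[2] - iv[1]))
                chains[name] = chain_for(name, l, l, [iv])
            return score_assembly(scores, chains, ref)
        r1 = build(["x", "y"], [0, 1])
        r2 = build(["b", "a"], [1, 0])
        assert r1.quality == pytest.approx(r2.quality, abs=1e-15)
        assert r1.delta == pytest.approx(r2.delta, abs=1e-15)
        assert r1.omega == pytest.approx(r2.omega, abs=1e-15)
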