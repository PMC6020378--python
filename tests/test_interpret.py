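"""Saliency, substitution maps, Fisher filtering, notation, zones."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guidenet.interpret import (SaliencyConfig, ZonePartition,
                                activation_maximize, duplex_to_substitution,
                                fisher_filter, project_simplex_rows,
                                substitution_count_tables,
                                substitution_effect_map,
                                substitution_to_duplex_notation,
                                zone_partition)
from guidenet.encoder import NUCLEOTIDES, PROTOSPACER_LEN


class ToyLinearScorer:
    """S(g) = sum over positions of the A channel, a linear objective whose
    simplex maximum is the all-A vertex."""

    def class_score(self, X, c=1):
        return X[:, :, 0].sum(axis=1)

    def input_grad(self, X, c=1):
        g = np.zeros_like(X)
        g[:, :, 0] = 1.0
        return g


class NanScorer(ToyLinearScorer):
    def input_grad(self, X, c=1):
        return np.full_like(X, np.nan)


class TestActivationMaximization:
    def test_linear_objective_reaches_all_a_vertex(self):
        smap = activation_maximize(ToyLinearScorer(), 1,
                                   SaliencyConfig(iterations=100, l2=0.0))
        assert np.allclose(smap.g[:, 0], 1.0, atol=1e-6)
        assert smap.top_bases() == "A" * 23

    def test_score_trace_is_ascending(self):
        smap = activation_maximize(ToyLinearScorer(), 1,
                                   SaliencyConfig(iterations=50))
        assert smap.trace[-1] >= smap.trace[0]

    def test_optimized_input_stays_feasible(self):
        smap = activation_maximize(ToyLinearScorer(), 1,
                                   SaliencyConfig(iterations=30))
        nuc = smap.g[:, :4]
        assert np.allclose(nuc.sum(axis=1), 1.0)
        assert (nuc >= 0).all()
        assert (smap.g[:, 4:] >= 0).all() and (smap.g[:, 4:] <= 1).all()

    def test_non_finite_gradient_aborts_with_trace(self):
        with pytest.raises(RuntimeError, match="trace"):
            activation_maximize(NanScorer(), 1, SaliencyConfig(iterations=5))


class TestSimplexProjection:
    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_projection_lands_on_simplex(self, row):
        out = project_simplex_rows(np.array([row]))
        assert out.min() >= 0
        assert out.sum() == pytest.approx(1.0)

    def test_projection_is_identity_on_simplex_points(self):
        pts = np.array([[0.25, 0.25, 0.25, 0.25], [1, 0, 0, 0],
                        [0.5, 0.3, 0.2, 0.0]])
        assert np.allclose(project_simplex_rows(pts), pts)


class MatchCountScorer:
    """Pair scorer: fraction of guide/site matches at positions 16-20, so
    substitutions there lower the score and substitutions at 1-15 do not."""

    def predict(self, Xg, Xs):
        m = (Xg[:, 15:20, :4] * Xs[:, 15:20, :4]).sum(axis=2)
        return m.mean(axis=1)


class TestSubstitutionEffectMap:
    def _background(self, rng, n=40):
        from guidenet import synth
        cfg = synth.SyntheticConfig(seed=17, n_pairs=n)
        ot = synth.gen_offtarget_set(config=cfg)
        return ot.Xg, ot.Xs

    def test_dimensions_and_identity_cells(self, rng):
        Xg, Xs = self._background(rng)
        emap = substitution_effect_map(MatchCountScorer(), Xg, Xs)
        assert emap.effects.shape == (20, 4, 4)
        assert np.array_equal(np.diagonal(emap.effects, axis1=1, axis2=2),
                              np.zeros((20, 4)))

    def test_planted_avoiding_zone_shows_negative_effects(self, rng):
        Xg, Xs = self._background(rng)
        avg = substitution_effect_map(MatchCountScorer(), Xg, Xs).averaged()
        assert (avg[15:20] < 0).all()
        assert np.allclose(avg[:15], 0.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            substitution_effect_map(MatchCountScorer(), np.zeros((0, 23, 8)),
                                    np.zeros((0, 23, 8)))


def fisher_two_sided_oracle(table):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := pmf(x)) <= p_obs * (1 + 1e-9))


class TestFisherFilter:
    def test_identical_proportions_give_p_one(self):
        p, mask = fisher_filter(np.array([[[5, 5], [5, 5]]]))
        assert p[0] == pytest.approx(1.0)
        assert not mask[0]

    def test_perfect_separation_p_value(self):
        p, mask = fisher_filter(np.array([[[10, 0], [0, 10]]]))
        assert p[0] == pytest.approx(1.082509e-5, rel=1e-4)
        assert p[0] == pytest.approx(
            fisher_two_sided_oracle([[10, 0], [0, 10]]), rel=1e-9)
        assert mask[0]

    def test_zero_margin_gives_p_one(self):
        p, _ = fisher_filter(np.array([[[0, 0], [3, 7]]]))
        assert p[0] == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_filter(np.array([[[-1, 0], [0, 1]]]))

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        tables = rng.integers(0, 12, size=(40, 2, 2))
        p, _ = fisher_filter(tables)
        for t, pv in zip(tables, p):
            assert pv == pytest.approx(fisher_two_sided_oracle(t), rel=1e-9)

    def test_bh_correction_never_more_permissive(self, rng):
        tables = rng.integers(0, 8, size=(30, 2, 2))
        _, raw = fisher_filter(tables, alpha=0.05)
        _, adj = fisher_filter(tables, alpha=0.05, bh_correct=True)
        assert (adj <= raw).all()


class TestCountTables:
    def test_margins_partition_the_pair_set(self):
        profiles = [((16, "G", "C"),), ((16, "G", "C"), (2, "A", "T")), ()]
        detected = [1, 0, 1]
        tables = substitution_count_tables(profiles, detected)
        t = tables[15, NUCLEOTIDES.index("G"), NUCLEOTIDES.index("C")]
        assert t.tolist() == [[1, 1], [1, 0]]
        assert tables.sum(axis=(3, 4)).max() == 3


class TestDuplexNotation:
    @pytest.mark.parametrize("X,Y,duplex", [
        ("G", "C", "rG:dG"),
        ("G", "T", "rG:dA"),
        ("A", "A", "rA:dT"),
    ])
    def test_printed_correspondences(self, X, Y, duplex):
        assert substitution_to_duplex_notation(X, Y) == duplex
        assert duplex_to_substitution(duplex) == (X, Y)

    def test_bijection_over_all_sixteen_cells(self):
        seen = set()
        for X in NUCLEOTIDES:
            for Y in NUCLEOTIDES:
                d = substitution_to_duplex_notation(X, Y)
                assert duplex_to_substitution(d) == (X, Y)
                seen.add(d)
        assert len(seen) == 16

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            substitution_to_duplex_notation("G", "N")
        with pytest.raises(ValueError):
            duplex_to_substitution("rG-dG")


class TestZonePartition:
    def test_all_zero_map_single_undetermined_zone(self):
        z = zone_partition(np.zeros(20), tau=0.1)
        assert z.ranges == [(1, 20, "undetermined")]

    def test_planted_three_zone_structure(self):
        avg = np.array([1.0] * 3 + [0.0] * 12 + [-1.0] * 5)
        z = zone_partition(avg, tau=0.5)
        assert z.ranges == [(1, 3, "preference"), (4, 15, "undetermined"),
                            (16, 20, "avoiding")]
        assert z.label_at(2) == "preference"
        assert z.label_at(18) == "avoiding"

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            zone_partition(np.zeros(19))

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-2, 2), min_size=20, max_size=20),
           st.floats(0.01, 1.0))
    def test_ranges_always_partition_1_to_20(self, avg, tau):
        z = zone_partition(np.array(avg), tau=tau)
        covered = []
        for lo, hi, label in z.ranges:
            assert label in ("preference", "undetermined", "avoiding")
            covered += list(range(lo, hi + 1))
        assert covered == list(range(1, PROTOSPACER_LEN + 1))
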