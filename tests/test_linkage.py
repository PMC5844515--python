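import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beanmap import io, linkage, synthetic


def _matrix_from_counts(n, n_rec):
    """Two-marker matrix with exactly n informative lines, n_rec recombinant."""
    col1 = np.zeros(n, dtype=np.int8)
    col2 = np.zeros(n, dtype=np.int8)
    col2[:n_rec] = 1
    return io.GenotypeMatrix([f"L{i}" for i in range(n)], ["a", "b"],
                             np.column_stack([col1, col2]))


class TestKosambi:
    def test_closed_forms(self):
        assert linkage.kosambi_cm(0.0) == 0.0
        assert linkage.kosambi_cm(0.25) == pytest.approx(25 * math.log(3))
        assert linkage.kosambi_cm(0.1) == pytest.approx(25 * math.log(1.5))

    def test_cap_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert linkage.kosambi_cm(0.5) == 50.0
        with pytest.warns(UserWarning):
            assert linkage.kosambi_cm(0.6, max_cm=75.0) == 75.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            linkage.kosambi_cm(-0.01)

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(derandomize=True, max_examples=80)
    def test_inverse_composes_to_identity(self, r):
        assert linkage.kosambi_inv(linkage.kosambi_cm(r)) == pytest.approx(
            r, abs=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(0, 0.49, 200)
        d = linkage.kosambi_cm(r)
        assert np.all(np.diff(d) > 0)


class TestHaldaneWaddington:
    def test_correction_closed_form(self):
        assert linkage.haldane_waddington_correction(0.2) == pytest.approx(0.125)
        assert linkage.haldane_waddington_correction(0.0) == 0.0

    def test_cap_at_half(self):
        assert linkage.haldane_waddington_correction(0.45) == pytest.approx(
            min(0.45 / (2 * 0.55), 0.5))
        assert linkage.haldane_waddington_correction(0.6) == 0.5

    def test_round_trip_with_ril_fraction(self):
        r = np.linspace(0, 0.49, 50)
        R = linkage.ril_observed_fraction(r)
        np.testing.assert_allclose(
            linkage.haldane_waddington_correction(R), r, atol=1e-12)


class TestTwoPoint:
    def test_worked_example_50_lines_5_recombinant(self):
        res = linkage.estimate_rf(_matrix_from_counts(50, 5), "a", "b")
        assert res.R == pytest.approx(0.1)
        expected_lod = 5 * math.log10(0.2) + 45 * math.log10(1.8)
        assert res.lod == pytest.approx(expected_lod, abs=1e-9)
        assert expected_lod == pytest.approx(7.99, abs=0.01)

    def test_identical_columns(self):
        res = linkage.estimate_rf(_matrix_from_counts(40, 0), "a", "b")
        assert res.R == 0.0 and res.r == 0.0
        assert res.lod == pytest.approx(40 * math.log10(2))

    def test_lod_is_zero_at_half(self):
        res = linkage.estimate_rf(_matrix_from_counts(40, 20), "a", "b")
        assert res.lod == pytest.approx(0.0, abs=1e-12)

    def test_uninformative_sentinel(self):
        calls = np.array([[0, 2], [3, 1], [0, 3]], dtype=np.int8)
        m = io.GenotypeMatrix(["a", "b", "c"], ["m1", "m2"], calls)
        res = linkage.estimate_rf(m, "m1", "m2")
        assert not res.informative
        assert math.isnan(res.R)

    def test_table_matches_single_pair_estimates(self, ril_sim):
        matrix, _ = ril_sim
        table = linkage.two_point_table(matrix)
        for i, j in [(0, 1), (3, 17), (10, 40)]:
            single = linkage.estimate_rf(matrix, matrix.marker_ids[i],
                                         matrix.marker_ids[j])
            assert table.n[i, j] == single.n
            assert table.R[i, j] == pytest.approx(single.R)
            assert table.lod[i, j] == pytest.approx(single.lod)

    def test_adjacent_rf_unbiased(self):
        """Mean bias of adjacent corrected r-hat vs Haldane truth < 0.01."""
        biases = []
        for seed in range(10):
            g = synthetic.scaled_genome(n_chromosomes=2, markers_per_chrom=15,
                                        seed=seed)
            matrix, truth = synthetic.simulate_ril_population(
                g, synthetic.RILConfig(n_lines=200, seed=seed + 50))
            table = linkage.two_point_table(matrix)
            idx = {m: k for k, m in enumerate(table.marker_ids)}
            for chrom in g.chromosomes:
                ms = truth.chrom_markers(chrom.name)
                for a, b, r_true in zip(ms, ms[1:],
                                        truth.adjacent_r[chrom.name]):
                    biases.append(table.r[idx[a], idx[b]] - r_true)
        assert abs(np.mean(biases)) < 0.01


class TestGrouping:
    def test_single_edge(self, ril_sim):
        matrix, _ = ril_sim
        sub = matrix.subset(markers=matrix.marker_ids[:2])
        table = linkage.two_point_table(sub)
        assert linkage.group_markers(table) == [[0, 1]]

    def test_transitive_closure_chain(self):
        table = linkage.TwoPointTable(
            ["a", "b", "c"],
            n=np.full((3, 3), 100), n_rec=np.zeros((3, 3)),
            R=np.array([[0, .05, .45], [.05, 0, .05], [.45, .05, 0]]),
            r=np.array([[0, .03, .45], [.03, 0, .03], [.45, .03, 0]]),
            lod=np.array([[0, 8, 1], [8, 0, 8], [1, 8, 0]], dtype=float))
        assert linkage.group_markers(table) == [[0, 1, 2]]

    def test_simulation_recovers_chromosome_count(self, two_point):
        groups = [g for g in linkage.group_markers(two_point) if len(g) >= 2]
        assert len(groups) == 3
        assert sorted(len(g) for g in groups) == [20, 20, 20]

    def test_empty_table(self):
        table = linkage.TwoPointTable([], np.empty((0, 0)), np.empty((0, 0)),
                                      np.empty((0, 0)), np.empty((0, 0)),
                                      np.empty((0, 0)))
        assert linkage.group_markers(table) == []

    def test_invariant_under_marker_permutation(self, ril_sim):
        matrix, _ = ril_sim
        rng = np.random.default_rng(4)
        perm = rng.permutation(matrix.n_markers)
        shuffled = matrix.subset(markers=[matrix.marker_ids[i] for i in perm])
        g1 = {frozenset(matrix.marker_ids[i] for i in g)
              for g in linkage.group_markers(linkage.two_point_table(matrix))}
        g2 = {frozenset(shuffled.marker_ids[i] for i in g)
              for g in linkage.group_markers(linkage.two_point_table(shuffled))}
        assert g1 == g2


def _toy_table(r):
    """TwoPointTable from a symmetric distance matrix (LOD fixed high)."""
    k = len(r)
    r = np.asarray(r, dtype=float)
    return linkage.TwoPointTable([f"m{i}" for i in range(k)],
                                 n=np.full((k, k), 100),
                                 n_rec=np.zeros((k, k)),
                                 R=r.copy(), r=r,
                                 lod=np.full((k, k), 10.0))


class TestOrdering:
    def test_three_marker_consistent_order(self):
        r = np.array([[0, .05, .10], [.05, 0, .05], [.10, .05, 0]])
        assert linkage.order_markers([0, 1, 2], _toy_table(r)) == [0, 1, 2]

    def test_matches_brute_force_on_six_markers(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pos = np.sort(rng.uniform(0, 0.4, size=6))
            r = np.abs(pos[:, None] - pos[None, :])
            r += rng.normal(0, 0.01, size=r.shape)
            r = np.clip((r + r.T) / 2, 0, 0.5)
            np.fill_diagonal(r, 0)
            table = _toy_table(r)
            order = linkage.order_markers(list(range(6)), table)
            best = min(linkage._sarf(list(p), r)
                       for p in itertools.permutations(range(6)))
            assert linkage._sarf(order, r) == pytest.approx(best, abs=1e-12)

    def test_truth_order_recovered_noiseless(self):
        g = synthetic.scaled_genome(n_chromosomes=1, markers_per_chrom=20,
                                    cm_per_chrom=60.0, seed=8)
        matrix, truth = synthetic.simulate_ril_population(
            g, synthetic.RILConfig(n_lines=2000, missing_rate=0.0,
                                   het_rate=0.0, seed=9))
        table = linkage.two_point_table(matrix)
        order = linkage.order_markers(list(range(20)), table)
        assert order in (list(range(20)), list(range(19, -1, -1)))

    def test_disconnected_group_raises(self):
        r = np.full((4, 4), np.nan)
        np.fill_diagonal(r, 0)
        r[0, 1] = r[1, 0] = 0.05
        r[2, 3] = r[3, 2] = 0.05
        table = _toy_table(np.zeros((4, 4)))
        table.r = r
        with pytest.raises(ValueError, match="disconnected"):
            linkage.order_markers([0, 1, 2, 3], table)


class TestMapAssembly:
    def test_cumulative_kosambi_positions(self):
        r = np.array([[0, .1, .2], [.1, 0, .1], [.2, .1, 0]])
        gmap = linkage.assemble_map([[0, 1, 2]], _toy_table(r))
        d = 25 * math.log(1.2 / 0.8)
        np.testing.assert_allclose(gmap.groups[0].positions_cm,
                                   [0.0, d, 2 * d])
        assert d == pytest.approx(10.14, abs=0.01)

    def test_single_marker_group_has_zero_length(self):
        gmap = linkage.assemble_map([[0]], _toy_table(np.zeros((1, 1))))
        assert gmap.groups[0].length_cm == 0.0

    def test_length_invariant_under_reversal(self):
        r = np.array([[0, .1, .2], [.1, 0, .1], [.2, .1, 0]])
        fwd = linkage.assemble_map([[0, 1, 2]], _toy_table(r))
        rev = linkage.assemble_map([[2, 1, 0]], _toy_table(r))
        assert fwd.total_length_cm == pytest.approx(rev.total_length_cm)
        grp = fwd.groups[0].reversed_()
        assert grp.length_cm == pytest.approx(fwd.groups[0].length_cm)
        assert grp.markers == fwd.groups[0].markers[::-1]


class TestAnchors:
    def _map(self):
        return linkage.GeneticMap([
            linkage.LinkageGroup("LG01", ["a", "b", "c"], np.arange(3.0)),
            linkage.LinkageGroup("LG02", ["d", "e"], np.arange(2.0)),
        ])

    def test_majority_label(self):
        gmap, conflicts = linkage.place_anchors(
            self._map(), {"a": "Pv2", "b": "Pv2", "c": "Pv2"})
        assert gmap.groups[0].chromosome == "Pv2"
        assert gmap.groups[1].chromosome is None
        assert conflicts == []

    def test_tie_reports_conflict_and_stays_unlabeled(self):
        gmap, conflicts = linkage.place_anchors(
            self._map(), {"a": "Pv2", "b": "Pv5"})
        assert gmap.groups[0].chromosome is None
        assert conflicts[0]["type"] == "no_majority"

    def test_duplicate_chromosome_claim_warns(self):
        with pytest.warns(UserWarning, match="claim"):
            gmap, conflicts = linkage.place_anchors(
                self._map(), {"a": "Pv2", "b": "Pv2", "d": "Pv2", "e": "Pv2"})
        assert any(c["type"] == "duplicate_chromosome" for c in conflicts)

    def test_simulated_anchors_label_all_groups(self, two_point, ril_sim,
                                                small_genome):
        _, truth = ril_sim
        groups = [g for g in linkage.group_markers(two_point) if len(g) >= 2]
        ordered = [linkage.order_markers(g, two_point) for g in groups]
        gmap = linkage.assemble_map(ordered, two_point)
        anchors = {r.marker: r.chrom
                   for i, r in enumerate(truth.marker_table.itertuples())
                   if i % 4 == 0}
        gmap, conflicts = linkage.place_anchors(gmap, anchors)
        assert sorted(g.chromosome for g in gmap.groups) == \
            sorted(c.name for c in small_genome.chromosomes)
        assert conflicts == []


class TestSummary:
    def test_equal_counts_chi_square_is_zero(self):
        gmap = linkage.GeneticMap([
            linkage.LinkageGroup("LG01", ["a", "b"], np.array([0.0, 10.0])),
            linkage.LinkageGroup("LG02", ["c", "d"], np.array([0.0, 20.0])),
        ])
        s = linkage.map_summary(gmap)
        assert s["chi2"] == 0.0 and s["chi2_p"] == 1.0
        assert s["total_length_cm"] == pytest.approx(30.0)
        assert s["mean_group_length_cm"] == pytest.approx(15.0)
        assert s["mean_marker_spacing_cm"] == pytest.approx(7.5)

    def test_assay_success_bookkeeping(self):
        s = linkage.assay_success(100, 3, 7)
        assert s["n_usable"] == 90 and s["success_pct"] == 90.0
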