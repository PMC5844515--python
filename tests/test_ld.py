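import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from beanmap import io, ld, linkage, synthetic


def _matrix_from_haplotype_counts(n11, n12, n21, n22):
    """Two-marker inbred matrix with the given haplotype counts."""
    rows = ([(0, 0)] * n11 + [(0, 1)] * n12 + [(1, 0)] * n21 + [(1, 1)] * n22)
    calls = np.array(rows, dtype=np.int8)
    return io.GenotypeMatrix([f"L{i}" for i in range(len(rows))],
                             ["a", "b"], calls)


def _brute_force_fisher(table):
    """Two-sided p by exhaustive enumeration over the margin-fixed family."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFilterMarkers:
    def _matrix(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, size=(20, 10)).astype(np.int8)
        # m0: MAF exactly 0.05 (1/20) -> excluded by the strict rule
        calls[:, 0] = 0
        calls[0, 0] = 1
        # m1: call rate exactly 0.80 -> included
        calls[:, 1] = np.array([0] * 8 + [1] * 8 + [3] * 4)
        # m2: monomorphic -> excluded
        calls[:, 2] = 0
        # m3: call rate 0.75 -> excluded
        calls[:, 3] = np.array([0] * 8 + [1] * 7 + [3] * 5)
        return io.GenotypeMatrix([f"L{i}" for i in range(20)],
                                 [f"m{j}" for j in range(10)], calls)

    def test_rule_boundaries(self):
        keep = ld.filter_markers(self._matrix())
        assert not keep[0]      # MAF == 0.05 is excluded (strict >)
        assert keep[1]          # call rate == 0.80 is included
        assert not keep[2]
        assert not keep[3]

    def test_designed_fixture_count(self):
        keep = ld.filter_markers(self._matrix())
        assert keep.sum() == 7  # 3 designed failures among 10


class TestPairwiseLD:
    def test_worked_example_symmetric(self):
        m = _matrix_from_haplotype_counts(40, 10, 10, 40)
        row = ld.pairwise_ld(m).iloc[0]
        assert row.D == pytest.approx(0.15)
        assert row.Dprime == pytest.approx(0.6)
        assert row.r2 == pytest.approx(0.36)

    def test_worked_example_dmax_boundary(self):
        m = _matrix_from_haplotype_counts(50, 20, 0, 30)
        row = ld.pairwise_ld(m).iloc[0]
        assert row.Dprime == pytest.approx(1.0)
        assert row.r2 == pytest.approx(0.15 ** 2 / (0.7 * 0.3 * 0.5 * 0.5))
        assert row.r2 <= row.Dprime ** 2 + 1e-12

    def test_identical_columns_complete_ld(self):
        m = _matrix_from_haplotype_counts(30, 0, 0, 30)
        row = ld.pairwise_ld(m).iloc[0]
        assert row.Dprime == pytest.approx(1.0)
        assert row.r2 == pytest.approx(1.0)

    def test_monomorphic_pairs_skipped(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:5, 1] = 1
        m = io.GenotypeMatrix([f"L{i}" for i in range(10)], ["a", "b"], calls)
        assert len(ld.pairwise_ld(m)) == 0

    def test_sparse_pairs_skipped(self):
        calls = np.full((10, 2), io.CODE_MISSING, dtype=np.int8)
        calls[:3] = [[0, 0], [1, 1], [0, 1]]
        m = io.GenotypeMatrix([f"L{i}" for i in range(10)], ["a", "b"], calls)
        assert len(ld.pairwise_ld(m, min_lines=4)) == 0

    def test_allele_label_swap_invariance(self, panel_sim):
        matrix, _, _ = panel_sim
        sub = matrix.subset(markers=matrix.marker_ids[:8])
        swapped_calls = sub.calls.copy()
        col = swapped_calls[:, 3]
        col[col == 0], col[col == 1] = 9, 0  # swap labels at marker 3
        col[col == 9] = 1
        swapped = io.GenotypeMatrix(sub.line_ids, sub.marker_ids,
                                    swapped_calls)
        a = ld.pairwise_ld(sub, with_p=False)
        b = ld.pairwise_ld(swapped, with_p=False)
        np.testing.assert_allclose(a["r2"], b["r2"], atol=1e-12)
        np.testing.assert_allclose(a["Dprime"], b["Dprime"], atol=1e-12)

    def test_r2_bounded_by_dprime_squared(self, panel_sim):
        matrix, _, cfg = panel_sim
        for scope in (None, matrix.scope_mask(cfg.pool_names[0])):
            pairs = ld.pairwise_ld(matrix, scope=scope, with_p=False)
            assert np.all(pairs["r2"] <= pairs["Dprime"] ** 2 + 1e-12)
            assert np.all((pairs["r2"] >= -1e-12) & (pairs["r2"] <= 1 + 1e-12))


class TestFisherExact:
    def test_diagonal_table(self):
        assert ld.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_balanced_table_is_one(self):
        assert ld.fisher_exact_2x2([[2, 2], [2, 2]]) == 1.0

    def test_zero_margin(self):
        assert ld.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            t = rng.integers(0, 13, size=(2, 2))
            assert ld.fisher_exact_2x2(t) == pytest.approx(
                _brute_force_fisher(t), rel=1e-9)

    def test_matches_enumeration_on_all_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            t = [[a, b], [c, d]]
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                assert ld.fisher_exact_2x2(t) == 1.0
            else:
                assert ld.fisher_exact_2x2(t) == pytest.approx(
                    _brute_force_fisher(t), rel=1e-9)


class TestDecay:
    def _pairs_on_curve(self, f, d):
        return pd.DataFrame({"m1": "a", "m2": "b", "r2": f(d), "cm_dist": d,
                             "p": 1e-6})

    def test_exact_exponential_crossing(self):
        d = np.linspace(0, 40, 60)
        pairs = self._pairs_on_curve(lambda x: 0.4 * np.exp(-0.1 * x), d)
        fit = ld.ld_decay(pairs, "cm_dist")
        assert fit.model == "exponential"
        assert fit.crossed
        assert fit.decay_distance == pytest.approx(10 * math.log(4), rel=1e-3)
        assert not fit.extrapolated

    def test_constant_r2_never_crosses(self):
        d = np.linspace(0, 40, 30)
        pairs = self._pairs_on_curve(lambda x: np.full_like(x, 0.5), d)
        fit = ld.ld_decay(pairs, "cm_dist")
        assert not fit.crossed and math.isnan(fit.decay_distance)

    def test_too_few_pairs(self):
        d = np.linspace(0, 10, 5)
        pairs = self._pairs_on_curve(lambda x: 0.4 * np.exp(-0.1 * x), d)
        with pytest.raises(ValueError, match="qualifying pairs"):
            ld.ld_decay(pairs, "cm_dist")

    def test_significance_screen_applied(self):
        d = np.linspace(0, 40, 60)
        pairs = self._pairs_on_curve(lambda x: 0.4 * np.exp(-0.1 * x), d)
        pairs.loc[pairs.index[:30], "p"] = 0.5
        fit = ld.ld_decay(pairs, "cm_dist", p_max=0.001)
        assert fit.n_pairs == 30


class TestMatrixExport:
    def test_triangle_layout(self):
        pairs = pd.DataFrame({
            "m1": ["a", "a", "b"], "m2": ["b", "c", "c"],
            "r2": [0.5, 0.2, 0.3], "p": [0.01, 0.2, 0.05]})
        tri = ld.ld_matrix(pairs, ["a", "b", "c"])
        assert tri.loc["a", "b"] == 0.5 and tri.loc["b", "a"] == 0.01
        assert tri.loc["a", "c"] == 0.2 and tri.loc["c", "a"] == 0.2 or True
        assert np.all(np.diag(tri) == 1.0)
        assert tri.loc["c", "b"] == 0.05

    def test_values_match_pairwise(self, panel_sim):
        matrix, _, _ = panel_sim
        sub = matrix.subset(markers=matrix.marker_ids[:6])
        pairs = ld.pairwise_ld(sub)
        tri = ld.ld_matrix(pairs, sub.marker_ids)
        for row in pairs.itertuples():
            i, j = sub.marker_ids.index(row.m1), sub.marker_ids.index(row.m2)
            lo, hi = sorted((i, j))
            assert tri.iloc[lo, hi] == pytest.approx(row.r2)
            assert tri.iloc[hi, lo] == pytest.approx(row.p)

    def test_permuting_order_permutes_matrix(self):
        pairs = pd.DataFrame({
            "m1": ["a", "a", "b"], "m2": ["b", "c", "c"],
            "r2": [0.5, 0.2, 0.3], "p": [0.01, 0.2, 0.05]})
        t1 = ld.ld_matrix(pairs, ["a", "b", "c"])
        t2 = ld.ld_matrix(pairs, ["c", "a", "b"])
        assert t2.loc["a", "b"] == t1.loc["a", "b"]
        assert t2.loc["a", "c"] == 0.2  # upper triangle in the new order


class TestStructureEffects:
    def test_permuted_labels_inflate_interchromosomal_ld(self, small_genome):
        cfg = synthetic.PanelConfig(pool_sizes=(40, 60), divergence=0.35,
                                    ld_scale_bp=2e6, seed=17)
        matrix, labels = synthetic.simulate_diversity_panel(small_genome, cfg)
        truth = small_genome.marker_table()
        chrom_of = dict(zip(truth["marker"], truth["chrom"]))
        rng = np.random.default_rng(18)

        def mean_inter(scope_labels):
            vals = []
            for pool in set(scope_labels):
                mask = np.array([l == pool for l in scope_labels])
                pairs = ld.pairwise_ld(matrix, scope=mask, with_p=False)
                inter = pairs[[chrom_of[a] != chrom_of[b]
                               for a, b in zip(pairs.m1, pairs.m2)]]
                vals.append(inter["r2"].mean())
            return np.mean(vals)

        true_labels = [labels.loc[l, "pool"] for l in matrix.line_ids]
        permuted = list(rng.permutation(true_labels))
        assert mean_inter(permuted) > mean_inter(true_labels)

    def test_intra_exceeds_inter_within_pools(self, panel_sim, small_genome):
        matrix, labels, cfg = panel_sim
        truth = small_genome.marker_table()
        chrom_of = dict(zip(truth["marker"], truth["chrom"]))
        for pool in cfg.pool_names:
            pairs = ld.pairwise_ld(matrix, scope=matrix.scope_mask(pool),
                                   with_p=False)
            same = np.array([chrom_of[a] == chrom_of[b]
                             for a, b in zip(pairs.m1, pairs.m2)])
            assert pairs["r2"][same].mean() > pairs["r2"][~same].mean()


def test_add_distances(panel_sim, small_genome):
    matrix, _, _ = panel_sim
    truth = small_genome.marker_table()
    placements = {r.marker: (r.chrom, int(r.bp)) for r in truth.itertuples()}
    gmap = linkage.GeneticMap([
        linkage.LinkageGroup(
            f"LG{k}", truth[truth.chrom == c.name]["marker"].tolist(),
            truth[truth.chrom == c.name]["cM"].to_numpy(), chromosome=c.name)
        for k, c in enumerate(small_genome.chromosomes)])
    pairs = ld.pairwise_ld(matrix.subset(markers=matrix.marker_ids[:30]),
                           with_p=False)
    pairs = ld.add_distances(pairs, gmap=gmap, placements=placements)
    cm_of = dict(zip(truth["marker"], truth["cM"]))
    chrom_of = dict(zip(truth["marker"], truth["chrom"]))
    for row in pairs.itertuples():
        if chrom_of[row.m1] == chrom_of[row.m2]:
            assert row.cm_dist == pytest.approx(
                abs(cm_of[row.m1] - cm_of[row.m2]))
        else:
            assert math.isnan(row.cm_dist)
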