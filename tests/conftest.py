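import pytest

from beanmap import linkage, synthetic


@pytest.fixture(scope="session")
def small_genome():
    """3 chromosomes x 6 Mb, 60 cM each, central plateau, 20 markers each."""
    return synthetic.scaled_genome(n_chromosomes=3, chrom_length_bp=6_000_000,
                                   cm_per_chrom=60.0, markers_per_chrom=20,
                                   seed=101)


@pytest.fixture(scope="session")
def ril_sim(small_genome):
    matrix, truth = synthetic.simulate_ril_population(
        small_genome, synthetic.RILConfig(n_lines=200, seed=202))
    return matrix, truth


@pytest.fixture(scope="session")
def two_point(ril_sim):
    matrix, _ = ril_sim
    return linkage.two_point_table(matrix)


@pytest.fixture(scope="session")
def panel_sim(small_genome):
    cfg = synthetic.PanelConfig(pool_sizes=(40, 60), ld_scale_bp=2_000_000,
                                seed=303)
    matrix, labels = synthetic.simulate_diversity_panel(small_genome, cfg)
    return matrix, labels, cfg


def adjacency_recovery(gmap_groups, truth_table):
    """Fraction of true adjacent marker pairs preserved in estimated orders."""
    ok = tot = 0
    for markers in gmap_groups:
        chrom = truth_table.loc[truth_table["marker"] == markers[0],
                                "chrom"].iloc[0]
        true_ms = list(truth_table.loc[truth_table["chrom"] == chrom, "marker"])
        adj_true = {frozenset(p) for p in zip(true_ms, true_ms[1:])}
        adj_est = {frozenset(p) for p in zip(markers, markers[1:])}
        ok += len(adj_true & adj_est)
        tot += len(adj_true)
    return ok / tot if tot else float("nan")


def interval_jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else float("nan")
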