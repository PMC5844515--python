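"""Parameter-recovery studies on synthetic data with known truth.

These drive the package's self-validation: a reference-like 11-chromosome
genome is simulated, the full mapping/anchoring/landscape machinery is run,
and the results are scored against the generating truth (linkage-group
recovery, marker-order adjacency, pericentromeric-interval overlap, LD decay
direction between differently structured genepools, gene-density/rate
correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ld, linkage, marey, synthetic, windows


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else float("nan")


def adjacency_recovery(group_orders, truth_table) -> float:
    """Fraction of true adjacent marker pairs preserved in estimated orders."""
    ok = tot = 0
    for markers in group_orders:
        chrom = truth_table.loc[truth_table["marker"] == markers[0],
                                "chrom"].iloc[0]
        true_ms = list(truth_table.loc[truth_table["chrom"] == chrom,
                                       "marker"])
        adj_true = {frozenset(p) for p in zip(true_ms, true_ms[1:])}
        adj_est = {frozenset(p) for p in zip(markers, markers[1:])}
        ok += len(adj_true & adj_est)
        tot += len(adj_true)
    return ok / tot if tot else float("nan")


@dataclass
class RecoveryResult:
    n_groups: int
    adjacency: float            # fraction of true adjacencies preserved
    pcenr_jaccard_mean: float   # over chromosomes with covered plateaus
    pcenr_jaccard: dict[str, float]
    pcenr_unscored: list[str]   # plateaus mostly outside the marker span
    genome_ratio_est: float
    genome_ratio_truth: float
    map_vs_physical_r: float


def recovery_study(seed: int, n_markers: int = 700, n_lines: int = 200
                   ) -> RecoveryResult:
    """Map an 11-chromosome simulated RIL population and score grouping,
    ordering and pericentromeric-plateau recovery against truth.

    Markers are allocated proportional to genetic length (near-uniform map
    spacing), the recoverable design for an ordering study.
    """
    genome = synthetic.default_genome(n_markers=n_markers, seed=seed,
                                      allocation="map_length")
    matrix, truth = synthetic.simulate_ril_population(
        genome, synthetic.RILConfig(n_lines=n_lines, seed=seed + 1))
    table = linkage.two_point_table(matrix)
    groups = [g for g in linkage.group_markers(table) if len(g) >= 2]
    ordered = [linkage.order_markers(g, table) for g in groups]
    gmap = linkage.assemble_map(ordered, table)
    tt = truth.marker_table
    anchors = {r.marker: r.chrom for i, r in enumerate(tt.itertuples())
               if i % 5 == 0}
    gmap, _ = linkage.place_anchors(gmap, anchors)
    adjacency = adjacency_recovery([g.markers for g in gmap.groups], tt)

    curves = marey.build_marey(gmap, truth.placements)
    land = marey.landscape_summary(gmap, genome.chrom_lengths)
    floor = 0.1 * marey.genome_mean_rate(land)
    jaccards: dict[str, float] = {}
    unscored: list[str] = []
    for chrom in genome.chromosomes:
        curve = curves.get(chrom.name)
        truth_iv = chrom.pcenr[0]
        if curve is None or not curve.fittable:
            jaccards[chrom.name] = 0.0
            continue
        # a plateau can only be recovered where markers exist: plateaus
        # mostly outside the marker span (the telocentric case, where the
        # Marey points start deep inside the plateau) are reported but not
        # scored
        span = (curve.bp[0], curve.bp[-1])
        covered = max(0.0, min(truth_iv[1], span[1]) - max(truth_iv[0],
                                                           span[0]))
        if covered < 0.5 * (truth_iv[1] - truth_iv[0]):
            unscored.append(chrom.name)
        marey.fit_marey(curve)
        call = marey.detect_pcenr(curve, floor)
        jaccards[chrom.name] = (interval_jaccard(call.primary, truth_iv)
                                if call.primary else 0.0)
    scored = [v for k, v in jaccards.items() if k not in unscored]
    return RecoveryResult(
        n_groups=len(groups), adjacency=adjacency,
        pcenr_jaccard_mean=float(np.mean(scored)),
        pcenr_jaccard=jaccards, pcenr_unscored=unscored,
        genome_ratio_est=land.genome_ratio_cm_per_mb,
        genome_ratio_truth=round(genome.total_cm / (genome.total_bp / 1e6), 2),
        map_vs_physical_r=float(land.pearson_r))


def decay_direction_study(seeds, markers_per_chrom: int = 50) -> dict:
    """LD decay distance per genepool on panels where pool 2 carries stronger
    race substructure; returns per-seed distances and the count of seeds with
    pool-1 decay faster than pool-2."""
    results = []
    wins = 0
    for seed in seeds:
        genome = synthetic.scaled_genome(n_chromosomes=3,
                                         markers_per_chrom=markers_per_chrom,
                                         seed=seed)
        cfg = synthetic.PanelConfig(seed=seed + 100, ld_scale_bp=2_000_000)
        panel, _ = synthetic.simulate_diversity_panel(genome, cfg)
        truth = genome.marker_table()
        cm_of = dict(zip(truth["marker"], truth["cM"]))
        chrom_of = dict(zip(truth["marker"], truth["chrom"]))
        dist = {}
        for pool in cfg.pool_names:
            mask = panel.scope_mask(pool)
            keep = ld.filter_markers(panel, scope=mask)
            pairs = ld.pairwise_ld(panel, scope=mask, scope_name=pool,
                                   marker_mask=keep, with_p=False)
            pairs["cm_dist"] = [
                abs(cm_of[a] - cm_of[b]) if chrom_of[a] == chrom_of[b]
                else np.nan for a, b in zip(pairs["m1"], pairs["m2"])]
            pairs = pairs[np.isfinite(pairs["cm_dist"])].copy()
            pairs["p"] = ld.fisher_p_column(pairs)
            fit = ld.ld_decay(pairs, "cm_dist", scope_name=pool,
                              model="exponential")
            dist[pool] = fit.decay_distance if fit.crossed else np.inf
        results.append(dist)
        if dist[cfg.pool_names[0]] < dist[cfg.pool_names[1]]:
            wins += 1
    return {"per_seed": results, "wins": wins, "n_seeds": len(list(seeds))}


def gene_density_study(seed: int) -> windows.CorrelationResult:
    """Correlation of windowed gene counts with the fitted recombination rate
    on a genome whose gene density follows the crossover landscape."""
    genome = synthetic.scaled_genome(n_chromosomes=3, markers_per_chrom=30,
                                     seed=seed)
    genes = synthetic.simulate_gene_models(genome, genes_per_mb=40,
                                           seed=seed + 1)
    truth = genome.marker_table()
    curves = {}
    for chrom in genome.chromosomes:
        sub = truth[truth["chrom"] == chrom.name]
        gmap = linkage.GeneticMap([linkage.LinkageGroup(
            "LG", sub["marker"].tolist(), sub["cM"].to_numpy(),
            chromosome=chrom.name)])
        placements = {r.marker: (r.chrom, int(r.bp))
                      for r in sub.itertuples()}
        curves[chrom.name] = marey.fit_marey(
            marey.build_marey(gmap, placements)[chrom.name])
    win = windows.make_windows(genome.chrom_lengths)
    out = windows.annotate_windows(win, genes=genes, curves=curves)
    return windows.correlate(out["n_genes"], out["rate_cm_per_bp"])
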