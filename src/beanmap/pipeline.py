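"""End-to-end orchestration: simulate -> map -> anchor -> marey -> popgen ->
ld -> windows -> report, with seeded reproducibility and checksummed outputs.

Every stage is also usable standalone (and via the CLI subcommands); the
orchestrator simply wires their inputs together and echoes the resolved
configuration so a run can be repeated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchoring, io, ld, linkage, marey, popgen, synthetic, windows

log = logging.getLogger("beanmap")


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic run.

    Thresholds default to the analysis settings used throughout the package:
    LOD 6.0 grouping, E-value 1e-30 with 1e10 separation for placements,
    MAF > 0.05 and call rate >= 0.80 for LD, r^2 decay threshold 0.1,
    1 Mb windows at 200 kb steps, 5000 coalescent repetitions.
    """

    seed: int = 0
    # synthetic genome (scaled for a fast end-to-end run)
    n_chromosomes: int = 3
    chrom_length_bp: int = 6_000_000
    cm_per_chrom: float = 60.0
    markers_per_chrom: int = 40
    suppression: float = 0.05
    n_paralogs: int = 3
    flank_len: int = 60
    genes_per_mb: float = 30.0
    # RIL population
    n_lines: int = 150
    selfing_generations: int = 11
    missing_rate: float = 0.01
    het_rate: float = 0.005
    # diversity panel
    panel: bool = True
    pool_sizes: tuple[int, int] = (71, 115)
    divergence: float = 0.3
    # LD correlation length: ~8 cM on the scaled genome's 10 cM/Mb landscape
    panel_ld_scale_bp: int = 2_000_000
    # thresholds
    lod_min: float = 6.0
    r_max: float = 0.4
    e_threshold: float = 1e-30
    separation: float = 1e10
    maf_min: float = 0.05
    call_rate_min: float = 0.80
    r2_threshold: float = 0.1
    p_max: float = 0.001
    window_size: int = 1_000_000
    window_step: int = 200_000
    sfs_reps: int = 5000
    degree: int = 7

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(val)
            elif f.type in ("float",):
                kwargs[f.name] = float(val)
            elif f.type in ("bool",):
                kwargs[f.name] = val.lower() in ("1", "true", "yes")
            elif f.type.startswith("tuple"):
                kwargs[f.name] = tuple(int(x) for x in val.split(","))
            else:
                kwargs[f.name] = val
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic genome and write a report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 6)
    written: list[Path] = []

    def emit(name: str):
        p = outdir / name
        written.append(p)
        return p

    cfg.to_file(emit("resolved_config.txt"))
    report: dict = {"seed": cfg.seed}

    # --- simulate ------------------------------------------------------------
    log.info("stage simulate: genome, RIL population, panel, sequences")
    genome = synthetic.scaled_genome(
        cfg.n_chromosomes, cfg.chrom_length_bp, cfg.cm_per_chrom,
        cfg.markers_per_chrom, suppression=cfg.suppression, seed=seeds[0])
    truth_table = genome.marker_table()
    truth_table.to_csv(emit("truth_markers.tsv"), sep="\t", index=False)
    ril, truth = synthetic.simulate_ril_population(
        genome, synthetic.RILConfig(n_lines=cfg.n_lines,
                                    selfing_generations=cfg.selfing_generations,
                                    missing_rate=cfg.missing_rate,
                                    het_rate=cfg.het_rate, seed=seeds[1]))
    io.write_genotypes(ril, emit("ril_genotypes.tsv"))

    # --- map -----------------------------------------------------------------
    log.info("stage map: two-point estimation, grouping, ordering")
    tp = linkage.two_point_table(ril)
    groups = [g for g in linkage.group_markers(tp, cfg.lod_min, cfg.r_max)
              if len(g) >= 2]
    ordered = [linkage.order_markers(g, tp) for g in groups]
    gmap = linkage.assemble_map(ordered, tp)
    # every 5th marker in generating order acts as a chromosome anchor
    anchors = {row.marker: row.chrom
               for i, row in enumerate(truth_table.itertuples()) if i % 5 == 0}
    gmap, conflicts = linkage.place_anchors(gmap, anchors)
    io.write_map_tsv(gmap.to_frame(), emit("map.tsv"))
    pd.DataFrame(genome.chrom_lengths.items(),
                 columns=["chrom", "length_bp"]).to_csv(
        emit("chrom_lengths.tsv"), sep="\t", index=False)
    msum = linkage.map_summary(gmap)
    report["map"] = {
        "n_groups": msum["n_groups"], "n_markers": msum["n_markers"],
        "total_length_cm": round(msum["total_length_cm"], 2),
        "mean_group_length_cm": round(msum["mean_group_length_cm"], 2),
        "mean_marker_spacing_cm": round(msum["mean_marker_spacing_cm"], 3),
        "chi2_p": msum["chi2_p"], "anchor_conflicts": len(conflicts),
    }

    # --- anchor --------------------------------------------------------------
    log.info("stage anchor: synthetic sequences, search, classification")
    chroms, flanks, paralogs = synthetic.simulate_marker_sequences(
        genome, flank_len=cfg.flank_len, n_paralogs=cfg.n_paralogs,
        seed=seeds[2])
    io.write_fasta(chroms, emit("chromosomes.fasta"))
    io.write_fasta(flanks, emit("marker_flanks.fasta"))
    index = anchoring.GenomeIndex(chroms)
    hits: list[io.HitRecord] = []
    for marker, seq in flanks.items():
        hits.extend(anchoring.naive_search(marker, seq, index))
    io.write_blast_tab(hits, emit("hits.tsv"))
    decisions = anchoring.classify_all(hits, list(flanks),
                                       cfg.e_threshold, cfg.separation)
    psum = anchoring.placement_summary(decisions)
    report["anchor"] = psum | {"n_paralogs_injected": len(paralogs)}
    placements = {d.marker: (d.chrom, d.position_bp)
                  for d in decisions if d.status == "singleton"}
    pd.DataFrame([dataclasses.asdict(d) for d in decisions]).to_csv(
        emit("placements.tsv"), sep="\t", index=False)
    genes = synthetic.simulate_gene_models(genome, cfg.genes_per_mb,
                                           seed=seeds[3])
    io.write_gff3(genes, emit("genes.gff3"))
    overlaps = anchoring.marker_gene_overlap(decisions, genes)
    report["anchor"]["n_marker_gene_overlaps"] = len(overlaps)

    # --- marey ---------------------------------------------------------------
    log.info("stage marey: curve fits, rates, pCENR detection")
    curves = marey.build_marey(gmap, placements)
    land = marey.landscape_summary(gmap, genome.chrom_lengths)
    land.table.to_csv(emit("landscape.tsv"), sep="\t", index=False)
    mean_rate = marey.genome_mean_rate(land)
    truth_rate = genome.total_cm / (genome.total_bp / 1e6)
    pcenr_rows = []
    for chrom, curve in sorted(curves.items()):
        if not curve.fittable:
            continue
        marey.fit_marey(curve, degree=cfg.degree)
        call = marey.detect_pcenr(curve, 0.1 * mean_rate)
        for k, iv in enumerate(call.intervals):
            pcenr_rows.append((chrom, iv[0], iv[1],
                               "primary" if k == 0 else "secondary"))
    io.write_bed(pcenr_rows, emit("pcenr.bed"))
    report["marey"] = {
        "genome_ratio_cm_per_mb": land.genome_ratio_cm_per_mb,
        "truth_ratio_cm_per_mb": round(truth_rate, 2),
        "mean_chrom_ratio": land.mean_ratio, "sd_chrom_ratio": land.sd_ratio,
        "map_vs_physical_r": round(land.pearson_r, 3)
        if np.isfinite(land.pearson_r) else None,
        "n_pcenr": len(pcenr_rows),
    }

    # --- popgen / ld / windows on the diversity panel -------------------------
    curves_fitted = {c: v for c, v in curves.items() if v.fitted}
    pairs_global = None
    if cfg.panel:
        log.info("stage popgen: diversity panel statistics")
        panel_cfg = synthetic.PanelConfig(pool_sizes=cfg.pool_sizes,
                                          divergence=cfg.divergence,
                                          ld_scale_bp=cfg.panel_ld_scale_bp,
                                          seed=seeds[4])
        panel, labels = synthetic.simulate_diversity_panel(genome, panel_cfg)
        io.write_genotypes(panel, emit("panel_genotypes.tsv"))
        io.write_labels(labels, emit("panel_labels.tsv"))
        scopes = [("global", None)] + [
            (name, panel.scope_mask(name)) for name in panel_cfg.pool_names]
        div_frames, sfs_rows, report_pg = [], [], {}
        for name, mask in scopes:
            div = popgen.marker_diversity(panel, mask, scope_name=name)
            div_frames.append(div)
            counts, edges = popgen.folded_sfs(div["maf"])
            n_alleles = int(np.median(div["n"]))
            expect = popgen.neutral_sfs_expectation(
                max(n_alleles, 2), int(counts.sum()), reps=cfg.sfs_reps,
                seed=seeds[5])
            _, consistent = popgen.neutrality_comparison(counts, expect)
            report_pg[name] = {
                "mean_pi": round(float(np.nanmean(div["pi"])), 4),
                "mean_maf": round(float(np.nanmean(div["maf"])), 4),
                "neutral_consistent": consistent,
            }
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                sfs_rows.append((name, lo, hi, int(c)))
        pd.concat(div_frames).to_csv(emit("diversity.tsv"), sep="\t",
                                     index=False)
        pd.DataFrame(sfs_rows, columns=["scope", "maf_lo", "maf_hi", "count"]
                     ).to_csv(emit("sfs.tsv"), sep="\t", index=False)
        report["popgen"] = report_pg

        log.info("stage ld: pairwise LD and decay per scope")
        report_ld = {}
        pair_frames = []
        for name, mask in scopes:
            keep = ld.filter_markers(panel, cfg.maf_min, cfg.call_rate_min,
                                     scope=mask)
            pairs = ld.pairwise_ld(panel, scope=mask, scope_name=name,
                                   marker_mask=keep)
            pairs = ld.add_distances(pairs, gmap=gmap, placements=placements)
            pair_frames.append(pairs)
            if name == "global":
                pairs_global = pairs
            entry = {"n_markers": int(keep.sum()), "n_pairs": len(pairs),
                     "mean_r2": round(float(pairs["r2"].mean()), 4)}
            try:
                fit = ld.ld_decay(pairs, "cm_dist", scope_name=name,
                                  p_max=cfg.p_max,
                                  threshold=cfg.r2_threshold)
                entry["decay_model"] = fit.model
                entry["decay_distance_cm"] = (round(fit.decay_distance, 2)
                                              if fit.crossed else None)
            except ValueError as err:
                entry["decay_error"] = str(err)
            report_ld[name] = entry
        all_pairs = pd.concat(pair_frames)
        all_pairs.to_csv(emit("ld_pairs.tsv"), sep="\t", index=False)
        first = gmap.groups[0]
        tri = ld.ld_matrix(pairs_global, first.markers)
        tri.to_csv(emit("ld_matrix_lg1.tsv"), sep="\t")
        report["ld"] = report_ld

    log.info("stage windows: gene density, rate and r^2 per window")
    win = windows.make_windows(genome.chrom_lengths, cfg.window_size,
                               cfg.window_step)
    win = windows.annotate_windows(
        win, genes=genes, curves=curves_fitted, pairs=pairs_global,
        marker_pos=placements if pairs_global is not None else None)
    win.to_csv(emit("windows.tsv"), sep="\t", index=False)
    report_win = {}
    if "rate_cm_per_bp" in win.columns:
        corr = windows.correlate(win["n_genes"], win["rate_cm_per_bp"])
        report_win["genes_vs_rate"] = {"r": round(corr.r, 3),
                                       "p": corr.p, "note": corr.note}
    if "mean_r2_pct" in win.columns:
        try:
            corr = windows.correlate(win["n_genes"], win["mean_r2_pct"])
            report_win["genes_vs_r2"] = {"r": round(corr.r, 3), "p": corr.p,
                                         "note": corr.note}
        except ValueError:
            report_win["genes_vs_r2"] = None
    report["windows"] = report_win

    report["checksums"] = {p.name: _sha256(p) for p in written}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
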