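"""Marey maps: genetic (cM) vs physical (bp) marker positions per chromosome,
polynomial curve fits with an isotonic monotonicity adjustment, local
recombination rates, pericentromeric-plateau (pCENR) detection and the
genetic/physical landscape summary table.

The genome-wide G/P ratio is computed from summed cM and bp totals, which is
deliberately distinct from the mean of per-chromosome ratios: the two answer
different questions and both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .anchoring import PlacementDecision
from .linkage import GeneticMap, _round_half_up


@dataclass
class MareyCurve:
    """Paired (bp, cM) points on one chromosome plus the fitted curve."""

    chrom: str
    marker_ids: list[str]
    bp: np.ndarray
    cm: np.ndarray
    flagged: np.ndarray                  # discordant (monotonicity-breaking)
    fittable: bool
    reversed_orientation: bool = False
    degree: int | None = None
    grid_bp: np.ndarray | None = None
    grid_cm: np.ndarray | None = None    # isotonic-adjusted fitted values
    coef: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.grid_cm is not None

    @property
    def genetic_length_cm(self) -> float:
        self._require_fit()
        return float(self.grid_cm[-1] - self.grid_cm[0])

    def _require_fit(self) -> None:
        if not self.fitted:
            raise ValueError(f"{self.chrom}: curve has not been fitted")

    def fitted_cm(self, bp) -> np.ndarray:
        """Adjusted fitted genetic position; constant beyond the marker span."""
        self._require_fit()
        return np.interp(np.asarray(bp, dtype=float), self.grid_bp, self.grid_cm)

    def rate(self, bp) -> np.ndarray:
        """Local recombination rate (cM/Mb) from the adjusted fit."""
        self._require_fit()
        grid_mb = self.grid_bp / 1e6
        rates = np.gradient(self.grid_cm, grid_mb)
        out = np.interp(np.asarray(bp, dtype=float), self.grid_bp, rates)
        return out


def build_marey(gmap: GeneticMap,
                placements: Mapping[str, tuple[str, int]] | Sequence[PlacementDecision],
                tol_cm: float = 1e-6, min_points: int = 3
                ) -> dict[str, MareyCurve]:
    """Join map positions with physical placements per labeled chromosome.

    Orientation is chosen so cM correlates positively with bp (the genetic
    coordinate is reversed otherwise).  Points that break monotonicity by
    more than ``tol_cm`` against the isotonic regression of cM on bp are
    flagged but never dropped.  Chromosomes with fewer than ``min_points``
    shared markers are marked unfittable.
    """
    if not isinstance(placements, Mapping):
        placements = {p.marker: (p.chrom, p.position_bp)
                      for p in placements if p.status == "singleton"}
    curves: dict[str, MareyCurve] = {}
    for g in gmap.groups:
        if g.chromosome is None:
            continue
        pts = [(placements[m][1], cm, m)
               for m, cm in zip(g.markers, g.positions_cm)
               if m in placements and placements[m][0] == g.chromosome]
        if not pts:
            continue
        pts.sort()
        bp = np.array([p[0] for p in pts], dtype=float)
        cm = np.array([p[1] for p in pts], dtype=float)
        ids = [p[2] for p in pts]
        reversed_orientation = False
        if len(pts) >= 2 and np.ptp(cm) > 0:
            slope = np.corrcoef(bp, cm)[0, 1]
            if slope < 0:
                cm = cm.max() - cm
                reversed_orientation = True
        iso = IsotonicRegression(increasing=True).fit(bp, cm)
        flagged = np.abs(cm - iso.predict(bp)) > tol_cm
        curves[g.chromosome] = MareyCurve(
            chrom=g.chromosome, marker_ids=ids, bp=bp, cm=cm, flagged=flagged,
            fittable=len(pts) >= min_points,
            reversed_orientation=reversed_orientation)
    return curves


def fit_marey(curve: MareyCurve, degree: int = 7,
              grid_points: int = 512) -> MareyCurve:
    """Least-squares polynomial fit of cM on bp, projected to the nearest
    non-decreasing sequence (isotonic adjustment) on a dense grid so that
    derivative-based rates are never negative.  Duplicate bp positions are
    averaged before fitting."""
    if not curve.fittable:
        raise ValueError(f"{curve.chrom}: curve marked unfittable")
    bp_u, inv = np.unique(curve.bp, return_inverse=True)
    cm_u = np.zeros_like(bp_u, dtype=float)
    counts = np.zeros_like(bp_u, dtype=float)
    np.add.at(cm_u, inv, curve.cm)
    np.add.at(counts, inv, 1.0)
    cm_u /= counts
    if len(bp_u) < degree + 2:
        raise ValueError(f"{curve.chrom}: need at least degree+2 distinct "
                         f"points to fit degree {degree}")
    mb = bp_u / 1e6
    poly = np.polynomial.Polynomial.fit(mb, cm_u, degree)
    grid_bp = np.linspace(bp_u[0], bp_u[-1], grid_points)
    vals = poly(grid_bp / 1e6)
    adjusted = IsotonicRegression(increasing=True).fit_transform(grid_bp, vals)
    curve.degree = degree
    curve.coef = poly.convert().coef
    curve.grid_bp = grid_bp
    curve.grid_cm = adjusted
    return curve


@dataclass
class PcenrCall:
    chrom: str
    primary: tuple[int, int] | None
    secondary: list[tuple[int, int]] = field(default_factory=list)

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return ([self.primary] if self.primary else []) + self.secondary


def detect_pcenr(curve: MareyCurve, rate_floor: float) -> PcenrCall:
    """Maximal bp intervals where the local rate falls below ``rate_floor``
    (cM/Mb).  The largest interval is primary; others are secondary."""
    curve._require_fit()
    grid_mb = curve.grid_bp / 1e6
    seg_rates = np.diff(curve.grid_cm) / np.diff(grid_mb)
    below = seg_rates < rate_floor
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            intervals.append((int(round(curve.grid_bp[i])),
                              int(round(curve.grid_bp[j + 1]))))
            i = j + 1
        i += 1
    if not intervals:
        return PcenrCall(curve.chrom, None)
    intervals.sort(key=lambda iv: (-(iv[1] - iv[0]), iv[0]))
    return PcenrCall(curve.chrom, intervals[0], intervals[1:])


def local_rate(curve: MareyCurve, bp) -> np.ndarray:
    """Convenience wrapper: local recombination rate in cM/Mb at bp."""
    return curve.rate(bp)


# -- landscape summary ---------------------------------------------------------

@dataclass
class LandscapeSummary:
    table: pd.DataFrame            # chrom, cm, bp, ratio, bp_per_cm [...]
    genome_cm: float
    genome_bp: int
    genome_ratio_cm_per_mb: float  # from totals, 2 dp
    mean_ratio: float              # mean of per-chromosome ratios, 2 dp
    sd_ratio: float                # population SD (divisor n), 2 dp
    pearson_r: float               # cM length vs bp length
    pearson_p: float
    mean_group_length_cm: float | None = None
    mean_marker_spacing_cm: float | None = None


def summarize_landscape(per_chrom: pd.DataFrame,
                        n_markers: int | None = None,
                        totals: tuple[float, int] | None = None
                        ) -> LandscapeSummary:
    """Genetic/physical ratio arithmetic from per-chromosome (cm, bp) columns.

    Ratios are rounded half-up to 2 decimals (presentation convention);
    bp/cM to the nearest integer.  The genome-wide ratio is computed from the
    summed totals, the mean/SD from the per-chromosome ratios.  When the
    source table carries its own printed totals row, pass it as
    ``totals=(cm, bp)``: it then overrides the recomputed sums for the
    genome-level statistics (published map tables are not always internally
    consistent).
    """
    df = per_chrom.copy()
    if not {"chrom", "cm", "bp"} <= set(df.columns):
        raise ValueError("need columns chrom, cm, bp")
    df["ratio_cm_per_mb"] = [
        _round_half_up(c / (b / 1e6), 2) for c, b in zip(df["cm"], df["bp"])]
    df["bp_per_cm"] = [int(_round_half_up(b / c, 0)) if c > 0 else np.nan
                       for c, b in zip(df["cm"], df["bp"])]
    if totals is not None:
        genome_cm, genome_bp = float(totals[0]), int(totals[1])
    else:
        genome_cm = float(df["cm"].sum())
        genome_bp = int(df["bp"].sum())
    genome_ratio = _round_half_up(genome_cm / (genome_bp / 1e6), 2)
    ratios = df["ratio_cm_per_mb"].to_numpy(dtype=float)
    mean_ratio = _round_half_up(float(np.mean(ratios)), 2)
    sd_ratio = _round_half_up(float(np.std(ratios)), 2)  # population SD
    if len(df) >= 3 and np.ptp(df["cm"]) > 0 and np.ptp(df["bp"]) > 0:
        r, p = stats.pearsonr(df["cm"], df["bp"])
    else:
        r, p = np.nan, np.nan
    mean_len = _round_half_up(genome_cm / len(df), 1) if len(df) else None
    spacing = (_round_half_up(genome_cm / n_markers, 2)
               if n_markers else None)
    return LandscapeSummary(
        table=df, genome_cm=genome_cm, genome_bp=genome_bp,
        genome_ratio_cm_per_mb=genome_ratio, mean_ratio=mean_ratio,
        sd_ratio=sd_ratio, pearson_r=float(r), pearson_p=float(p),
        mean_group_length_cm=mean_len, mean_marker_spacing_cm=spacing)


def landscape_summary(gmap: GeneticMap, chrom_lengths: Mapping[str, int]
                      ) -> LandscapeSummary:
    """Landscape summary for a labeled map against physical chromosome
    lengths."""
    rows = []
    n_markers = 0
    for g in gmap.groups:
        if g.chromosome is None or g.chromosome not in chrom_lengths:
            continue
        rows.append((g.chromosome, g.length_cm, chrom_lengths[g.chromosome]))
        n_markers += len(g.markers)
    per_chrom = pd.DataFrame(rows, columns=["chrom", "cm", "bp"])
    return summarize_landscape(per_chrom, n_markers=n_markers or None)


def genome_mean_rate(summary: LandscapeSummary) -> float:
    """Genome-wide mean recombination rate (cM/Mb) from totals."""
    return summary.genome_cm / (summary.genome_bp / 1e6)
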