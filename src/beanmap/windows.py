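"""Sliding-window gene density, recombination rate and mean r^2.

Windows are 0-based half-open, start at 0 and advance by ``step``; a gene
belongs to a window when their intervals share at least 1 bp (containment
counting is available).  The window recombination rate is the fitted genetic
length across the window divided by its physical size (cM/bp); mean r^2 uses
only marker pairs with both markers inside the window and is expressed in
percent.  Overlapping windows are statistically dependent, so correlation
p-values carry a metadata caveat rather than a correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel
from .marey import MareyCurve

DEPENDENCE_NOTE = ("overlapping sliding windows are statistically dependent; "
                   "p-values are not corrected for this")


def make_windows(chrom_lengths: Mapping[str, int], size: int = 1_000_000,
                 step: int = 200_000) -> pd.DataFrame:
    """Window skeletons per chromosome.  Chromosomes shorter than ``size``
    yield a single truncated, flagged window."""
    if size < step:
        raise ValueError("window size must be >= step")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < size:
            rows.append((chrom, 0, int(length), True))
            continue
        n = (length - size) // step + 1
        for k in range(int(n)):
            rows.append((chrom, k * step, k * step + size, False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "truncated"])


def annotate_windows(windows: pd.DataFrame,
                     genes: Sequence[GeneModel] | None = None,
                     curves: Mapping[str, MareyCurve] | None = None,
                     pairs: pd.DataFrame | None = None,
                     marker_pos: Mapping[str, tuple[str, int]] | None = None,
                     gene_mode: str = "overlap") -> pd.DataFrame:
    """Fill gene counts, recombination rates and mean r^2 (%) per window."""
    if gene_mode not in ("overlap", "contained"):
        raise ValueError("gene_mode must be 'overlap' or 'contained'")
    df = windows.copy()
    ws = df["start"].to_numpy()
    we = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()

    if genes is not None:
        counts = np.zeros(len(df), dtype=int)
        for chrom in pd.unique(chroms):
            sub = [g for g in genes if g.chrom == chrom]
            gs = np.array([g.start for g in sub])
            ge = np.array([g.end for g in sub])
            idx = np.flatnonzero(chroms == chrom)
            for k in idx:
                if gene_mode == "overlap":
                    counts[k] = int(np.sum((gs < we[k]) & (ge > ws[k])))
                else:
                    counts[k] = int(np.sum((gs >= ws[k]) & (ge <= we[k])))
        df["n_genes"] = counts

    if curves is not None:
        rates = np.full(len(df), np.nan)
        for chrom, curve in curves.items():
            if not curve.fitted:
                continue
            idx = np.flatnonzero(chroms == chrom)
            span = (we[idx] - ws[idx]).astype(float)
            rates[idx] = (curve.fitted_cm(we[idx]) - curve.fitted_cm(ws[idx])) / span
        df["rate_cm_per_bp"] = rates

    if pairs is not None:
        if marker_pos is None:
            raise ValueError("marker_pos is required to window LD pairs")
        mean_r2 = np.full(len(df), np.nan)
        n_pairs = np.zeros(len(df), dtype=int)
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(chroms):
            rows = [(min(marker_pos[a][1], marker_pos[b][1]),
                     max(marker_pos[a][1], marker_pos[b][1]), r2)
                    for a, b, r2 in zip(pairs["m1"], pairs["m2"], pairs["r2"])
                    if a in marker_pos and b in marker_pos
                    and marker_pos[a][0] == chrom and marker_pos[b][0] == chrom]
            if rows:
                arr = np.array(rows, dtype=float)
                by_chrom[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        for k in range(len(df)):
            if chroms[k] not in by_chrom:
                continue
            lo, hi, r2 = by_chrom[chroms[k]]
            # positions are 1-based bp; window interval is 0-based half-open
            inside = (lo - 1 >= ws[k]) & (hi - 1 < we[k])
            n_pairs[k] = int(inside.sum())
            if n_pairs[k] >= 1:
                mean_r2[k] = 100.0 * float(r2[inside].mean())
        df["mean_r2_pct"] = mean_r2
        df["n_pairs"] = n_pairs
    return df


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    note: str = DEPENDENCE_NOTE


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation over paired finite values; zero variance gives a NaN
    sentinel rather than an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), method)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(float(r), float(p), len(x), method)
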