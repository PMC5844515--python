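"""Two-point RIL linkage mapping: recombination fractions, LOD grouping,
marker ordering, Kosambi distances, anchor placement and map summaries.

The population is an advanced-selfing RIL, so the observed recombinant-line
fraction R overestimates the per-meiosis fraction r; the Haldane-Waddington
relation R = 2r/(1+2r) is inverted (r = R/(2(1-R))) before map distances are
computed, and the Kosambi function d = 25 ln((1+2r)/(1-2r)) converts r to cM.

Heterozygous and missing calls are excluded pairwise; a line is informative
for a marker pair only when both calls are parental (A or B).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .io import CODE_A, CODE_B, GenotypeMatrix


# -- map functions ------------------------------------------------------------

def kosambi_cm(r, max_cm: float = 50.0):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM.

    Values r >= 0.5 are capped at ``max_cm`` with a warning.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("recombination fraction must be >= 0")
    capped = r_arr >= 0.5
    if np.any(capped):
        warnings.warn(f"capping {int(np.sum(capped))} distance(s) with r >= 0.5 "
                      f"at {max_cm} cM", stacklevel=2)
    safe = np.where(capped, 0.0, r_arr)
    d = 25.0 * np.log((1.0 + 2.0 * safe) / (1.0 - 2.0 * safe))
    d = np.where(capped, max_cm, d)
    return float(d) if np.isscalar(r) else d


def kosambi_inv(d_cm):
    """Inverse Kosambi: r = tanh(d/50) / 2."""
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if np.isscalar(d_cm) else r


def haldane_waddington_correction(R):
    """Meiotic r from the observed RIL fraction: r = R/(2(1-R)), capped at 0.5."""
    R_arr = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = R_arr / (2.0 * (1.0 - R_arr))
    r = np.where(np.isnan(R_arr), np.nan, np.minimum(r, 0.5))
    return float(r) if np.isscalar(R) else r


def ril_observed_fraction(r):
    """Expected recombinant-line fraction at F-infinity: R = 2r/(1+2r)."""
    r_arr = np.asarray(r, dtype=float)
    R = 2.0 * r_arr / (1.0 + 2.0 * r_arr)
    return float(R) if np.isscalar(r) else R


# -- two-point estimation -----------------------------------------------------

@dataclass(frozen=True)
class TwoPointResult:
    m1: str
    m2: str
    n: int           # informative lines (both calls parental)
    n_rec: int       # recombinant lines
    R: float         # observed RIL fraction (nan if n < 2)
    r: float         # Haldane-Waddington corrected meiotic fraction
    lod: float

    @property
    def informative(self) -> bool:
        return self.n >= 2


@dataclass
class TwoPointTable:
    """All-pairs two-point statistics as square arrays over marker index."""

    marker_ids: list[str]
    n: np.ndarray
    n_rec: np.ndarray
    R: np.ndarray
    r: np.ndarray
    lod: np.ndarray

    def result(self, i: int, j: int) -> TwoPointResult:
        return TwoPointResult(self.marker_ids[i], self.marker_ids[j],
                              int(self.n[i, j]), int(self.n_rec[i, j]),
                              float(self.R[i, j]), float(self.r[i, j]),
                              float(self.lod[i, j]))


def _lod(n: np.ndarray, n_rec: np.ndarray, R: np.ndarray) -> np.ndarray:
    """LOD = n_R log10(2R) + (n - n_R) log10(2(1-R)) with 0 log 0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n_rec > 0, n_rec * np.log10(2.0 * R), 0.0)
        t2 = np.where(n - n_rec > 0, (n - n_rec) * np.log10(2.0 * (1.0 - R)), 0.0)
    return t1 + t2


def two_point_table(matrix: GenotypeMatrix) -> TwoPointTable:
    """Compute every pairwise recombination fraction and LOD score."""
    calls = matrix.calls
    A = (calls == CODE_A).astype(np.float64)
    B = (calls == CODE_B).astype(np.float64)
    V = A + B
    n = V.T @ V
    same = A.T @ A + B.T @ B
    n_rec = n - same
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n >= 2, n_rec / n, np.nan)
    r = haldane_waddington_correction(R)
    lod = np.where(n >= 2, _lod(n, n_rec, np.where(np.isnan(R), 0.0, R)), np.nan)
    return TwoPointTable(list(matrix.marker_ids), n.astype(np.int64),
                         n_rec.astype(np.int64), R, r, lod)


def estimate_rf(matrix: GenotypeMatrix, m1: str, m2: str) -> TwoPointResult:
    """Two-point estimate for one marker pair.

    Pairs with fewer than 2 informative lines are returned as an
    uninformative sentinel (nan statistics, ``informative`` False).
    """
    i, j = matrix.marker_index(m1), matrix.marker_index(m2)
    c1, c2 = matrix.calls[:, i], matrix.calls[:, j]
    ok = ((c1 == CODE_A) | (c1 == CODE_B)) & ((c2 == CODE_A) | (c2 == CODE_B))
    n = int(np.sum(ok))
    if n < 2:
        return TwoPointResult(m1, m2, n, 0, float("nan"), float("nan"),
                              float("nan"))
    n_rec = int(np.sum(c1[ok] != c2[ok]))
    R = n_rec / n
    lod = float(_lod(np.array(n, dtype=float), np.array(n_rec, dtype=float),
                     np.array(R)))
    return TwoPointResult(m1, m2, n, n_rec, R,
                          float(haldane_waddington_correction(R)), lod)


# -- grouping and ordering ----------------------------------------------------

def group_markers(table: TwoPointTable, lod_min: float = 6.0,
                  r_max: float = 0.4) -> list[list[int]]:
    """Single-linkage transitive closure over pairs with LOD >= lod_min and
    r <= r_max.  Groups are numbered by their smallest marker index; markers
    without any qualifying edge form singleton groups."""
    m = len(table.marker_ids)
    if m == 0:
        return []
    with np.errstate(invalid="ignore"):
        adj = (table.lod >= lod_min) & (table.r <= r_max) & (table.n >= 2)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(sparse.csr_matrix(adj),
                                          directed=False)
    groups = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
    groups.sort(key=lambda g: g[0])
    return groups


def high_lod_markers(table: TwoPointTable, lod_min: float = 6.0) -> list[int]:
    """Markers retained for the refined map: those linked to at least one
    other marker at LOD >= lod_min."""
    with np.errstate(invalid="ignore"):
        adj = np.nan_to_num(table.lod, nan=-np.inf) >= lod_min
    np.fill_diagonal(adj, False)
    return np.flatnonzero(adj.any(axis=1)).tolist()


def _sarf(order: Sequence[int], d: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(d[idx[:-1], idx[1:]].sum())


def order_markers(group: Sequence[int], table: TwoPointTable) -> list[int]:
    """Order a linkage group by minimising the sum of adjacent recombination
    fractions (SARF): greedy nearest-neighbour construction, 2-opt refinement,
    then exhaustive polish of 4-marker windows.  Deterministic (ties resolved
    toward the lower marker index); the returned order starts at the smaller
    terminal index."""
    group = list(group)
    k = len(group)
    if k < 2:
        return group
    d_full = table.r
    d = d_full[np.ix_(group, group)].copy()
    missing = ~np.isfinite(d)
    np.fill_diagonal(missing, False)
    if missing.any():
        # pairs without an estimate: check connectivity on the finite graph
        finite = np.isfinite(d)
        np.fill_diagonal(finite, True)
        n_comp, _ = connected_components(sparse.csr_matrix(finite),
                                         directed=False)
        if n_comp > 1:
            raise ValueError("group is disconnected: no finite recombination "
                             "path covers all markers")
        d[missing] = 0.5
    np.fill_diagonal(d, np.inf)

    # greedy construction from the tightest pair
    start = np.unravel_index(np.argmin(d), d.shape)
    path = [min(start), max(start)]
    used = set(path)
    while len(path) < k:
        best = None  # (dist, marker_local, end) with deterministic ties
        for end_pos, end in ((0, path[0]), (-1, path[-1])):
            for cand in range(k):
                if cand in used:
                    continue
                key = (d[end, cand], cand, end_pos)
                if best is None or key < best:
                    best = key
        _, cand, end_pos = best
        if end_pos == 0:
            path.insert(0, cand)
        else:
            path.append(cand)
        used.add(cand)

    path = _two_opt(path, d)
    path = _window_polish(path, d, width=4)
    if group[path[0]] > group[path[-1]]:
        path = path[::-1]
    return [group[i] for i in path]


def _two_opt(path: list[int], d: np.ndarray, tol: float = 1e-12) -> list[int]:
    k = len(path)
    improved = True
    while improved:
        improved = False
        best_delta, best_move = -tol, None
        p = np.asarray(path)
        for i in range(k - 1):
            left = d[p[i - 1], p[i]] if i > 0 else 0.0
            for j in range(i + 1, k):
                right = d[p[j], p[j + 1]] if j < k - 1 else 0.0
                new_left = d[p[i - 1], p[j]] if i > 0 else 0.0
                new_right = d[p[i], p[j + 1]] if j < k - 1 else 0.0
                delta = new_left + new_right - left - right
                if delta < best_delta:
                    best_delta, best_move = delta, (i, j)
        if best_move is not None:
            i, j = best_move
            path[i:j + 1] = path[i:j + 1][::-1]
            improved = True
    return path


def _window_polish(path: list[int], d: np.ndarray, width: int = 4,
                   max_rounds: int = 20) -> list[int]:
    k = len(path)
    if k <= width:
        perms = itertools.permutations(range(k))
        best = min(perms, key=lambda p: (_sarf([path[i] for i in p], d), p))
        return [path[i] for i in best]
    for _ in range(max_rounds):
        changed = False
        for s in range(k - width + 1):
            window = path[s:s + width]
            left = path[s - 1] if s > 0 else None
            right = path[s + width] if s + width < k else None

            def cost(w):
                c = _sarf(w, d)
                if left is not None:
                    c += d[left, w[0]]
                if right is not None:
                    c += d[w[-1], right]
                return c

            base = cost(window)
            best_w, best_c = window, base
            for perm in itertools.permutations(window):
                perm = list(perm)
                c = cost(perm)
                if c < best_c - 1e-12:
                    best_w, best_c = perm, c
            if best_w != window:
                path[s:s + width] = best_w
                changed = True
        if not changed:
            break
    return path


# -- map assembly -------------------------------------------------------------

@dataclass
class LinkageGroup:
    name: str
    markers: list[str]
    positions_cm: np.ndarray
    chromosome: str | None = None

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1] - self.positions_cm[0]) \
            if len(self.positions_cm) else 0.0

    def reversed_(self) -> "LinkageGroup":
        pos = self.positions_cm[-1] - self.positions_cm[::-1]
        return LinkageGroup(self.name, self.markers[::-1], pos, self.chromosome)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    @property
    def n_markers(self) -> int:
        return int(sum(len(g.markers) for g in self.groups))

    def to_frame(self, placements: Mapping[str, tuple[str, int]] | None = None
                 ) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for marker, cm in zip(g.markers, g.positions_cm):
                chrom, bp = "", ""
                if placements and marker in placements:
                    chrom, bp = placements[marker]
                rows.append((g.name, marker, round(float(cm), 4),
                             g.chromosome or chrom, bp))
        return pd.DataFrame(rows, columns=["linkage_group", "marker", "cM",
                                           "chromosome", "bp"])


def assemble_map(ordered_groups: Sequence[Sequence[int]],
                 table: TwoPointTable, max_cm: float = 50.0) -> GeneticMap:
    """Cumulative Kosambi positions from adjacent corrected fractions."""
    groups = []
    for gi, order in enumerate(ordered_groups):
        ids = [table.marker_ids[i] for i in order]
        if len(order) == 1:
            groups.append(LinkageGroup(f"LG{gi + 1:02d}", ids, np.zeros(1)))
            continue
        idx = np.asarray(order)
        adj_r = table.r[idx[:-1], idx[1:]]
        adj_r = np.where(np.isfinite(adj_r), adj_r, 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = kosambi_cm(adj_r, max_cm=max_cm)
        pos = np.concatenate([[0.0], np.cumsum(d)])
        groups.append(LinkageGroup(f"LG{gi + 1:02d}", ids, pos))
    return GeneticMap(groups)


def place_anchors(gmap: GeneticMap, anchors: Mapping[str, str]
                  ) -> tuple[GeneticMap, list[dict]]:
    """Label linkage groups by the majority chromosome of their anchor
    markers.  Conflicts (no strict majority, or two groups claiming the same
    chromosome) are reported, not resolved."""
    conflicts: list[dict] = []
    claimed: dict[str, str] = {}
    new_groups = []
    for g in gmap.groups:
        counts = Counter(anchors[m] for m in g.markers if m in anchors)
        label = None
        if counts:
            top, top_n = counts.most_common(1)[0]
            if top_n * 2 > sum(counts.values()):
                label = top
            else:
                conflicts.append({"group": g.name, "type": "no_majority",
                                  "labels": dict(counts)})
        if label is not None and label in claimed:
            conflicts.append({"group": g.name, "type": "duplicate_chromosome",
                              "chromosome": label,
                              "also_claimed_by": claimed[label]})
            warnings.warn(f"{g.name} and {claimed[label]} both claim {label}")
        if label is not None:
            claimed.setdefault(label, g.name)
        new_groups.append(LinkageGroup(g.name, list(g.markers),
                                       g.positions_cm.copy(), label))
    return GeneticMap(new_groups), conflicts


def assay_success(n_markers: int, n_heterozygous: int, n_low_signal: int) -> dict:
    """Genotyping bookkeeping: markers usable after removing heterozygous and
    low-signal assays, and the success percentage (1 decimal)."""
    n_usable = n_markers - n_heterozygous - n_low_signal
    return {"n_markers": n_markers, "n_usable": n_usable,
            "success_pct": _round_half_up(100.0 * n_usable / n_markers, 1)}


def map_summary(gmap: GeneticMap) -> dict:
    """Per-group and total map statistics plus a chi-square test of marker
    counts against a uniform expectation across groups."""
    rows = [(g.name, g.chromosome, len(g.markers), round(g.length_cm, 4))
            for g in gmap.groups]
    per_group = pd.DataFrame(rows, columns=["linkage_group", "chromosome",
                                            "n_markers", "length_cm"])
    total_cm = gmap.total_length_cm
    n_markers = gmap.n_markers
    n_groups = len(gmap.groups)
    counts = per_group["n_markers"].to_numpy()
    if n_groups > 1 and counts.sum() > 0:
        chi2, p = stats.chisquare(counts)
        df = n_groups - 1
    else:
        chi2, p, df = 0.0, 1.0, 0
    return {
        "per_group": per_group,
        "total_length_cm": total_cm,
        "n_markers": n_markers,
        "n_groups": n_groups,
        "mean_group_length_cm": total_cm / n_groups if n_groups else 0.0,
        "mean_marker_spacing_cm": total_cm / n_markers if n_markers else 0.0,
        "chi2": float(chi2),
        "chi2_df": df,
        "chi2_p": float(p),
    }


def _round_half_up(x: float, nd: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -nd
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
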