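"""Pairwise linkage disequilibrium for inbred (haplotype-like) genotypes.

Fully selfed lines are treated as haplotypes: residual heterozygous and
missing calls are excluded pairwise, and for a marker pair the four
haplotype counts (n11, n12, n21, n22) give

    D   = p11 - pA * pB
    D'  = |D| / Dmax,  Dmax = min(pA qB, qA pB) if D > 0
                              else min(pA pB, qA qB)
    r^2 = D^2 / (pA qA pB qB)

with the guaranteed relation r^2 <= D'^2.  Two-sided p-values come from
Fisher's exact test (point-probability method).  Decay curves are fitted to
r^2 vs distance for pairs passing a significance screen, using either a
second-degree polynomial or an exponential tendency line a*exp(-b d)
(chosen by an F-test of the exponential against a constant model).

The significance screen induces a selection floor: with n lines, a pair is
only significant when r^2 exceeds roughly chi2/n, so screened long-distance
points hover at that floor.  An exponential with a free offset would
asymptote at the floor and never reach a lower threshold; the offset-free
tendency line decays through it, which is how the decay-to-threshold
distance is defined here (flagged as extrapolated when the crossing lies
beyond the observed distance range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CODE_A, CODE_B, CODE_MISSING, GenotypeMatrix
from .linkage import GeneticMap


def filter_markers(matrix: GenotypeMatrix, maf_min: float = 0.05,
                   call_rate_min: float = 0.80,
                   scope: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of markers kept for LD analysis: MAF strictly above
    ``maf_min`` and non-missing call fraction at least ``call_rate_min``."""
    calls = matrix.calls if scope is None else matrix.calls[scope]
    n_lines = calls.shape[0]
    call_rate = np.sum(calls != CODE_MISSING, axis=0) / n_lines
    nA = np.sum(calls == CODE_A, axis=0)
    nB = np.sum(calls == CODE_B, axis=0)
    n = nA + nB
    # MAF from integer counts so the strict boundary is exact
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(n > 0, np.minimum(nA, nB) / n, np.nan)
        keep = (m > maf_min) & (call_rate >= call_rate_min)
    return np.where(np.isnan(m), False, keep)


def fisher_exact_2x2(counts) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method:
    sum of hypergeometric probabilities <= the observed table's)."""
    table = np.asarray(counts, dtype=np.int64).reshape(2, 2)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pairwise_ld(matrix: GenotypeMatrix, scope: np.ndarray | None = None,
                scope_name: str = "global",
                marker_mask: np.ndarray | None = None,
                with_p: bool = True, min_lines: int = 4) -> pd.DataFrame:
    """LD table over all marker pairs within a line scope.

    Pairs monomorphic in scope or with fewer than ``min_lines`` informative
    lines are skipped.  Columns: m1, m2, scope, n, n11, n12, n21, n22, D,
    Dprime, r2 and (optionally) the Fisher p-value.
    """
    calls = matrix.calls if scope is None else matrix.calls[scope]
    if marker_mask is not None:
        keep_idx = np.flatnonzero(marker_mask)
    else:
        keep_idx = np.arange(matrix.n_markers)
    ids = [matrix.marker_ids[i] for i in keep_idx]
    sub = calls[:, keep_idx]
    A = (sub == CODE_A).astype(np.float64)
    B = (sub == CODE_B).astype(np.float64)
    n11 = A.T @ A
    n12 = A.T @ B
    n21 = B.T @ A
    n22 = B.T @ B
    n = n11 + n12 + n21 + n22
    iu, ju = np.triu_indices(len(keep_idx), k=1)
    c11, c12, c21, c22 = (m[iu, ju] for m in (n11, n12, n21, n22))
    cn = n[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (c11 + c12) / cn
        pB = (c11 + c21) / cn
        qA, qB = 1.0 - pA, 1.0 - pB
        valid = (cn >= min_lines) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
        D = c11 / cn - pA * pB
        dmax = np.where(D >= 0, np.minimum(pA * qB, qA * pB),
                        np.minimum(pA * pB, qA * qB))
        dprime = np.abs(D) / dmax
        r2 = D ** 2 / (pA * qA * pB * qB)
    sel = np.flatnonzero(valid)
    df = pd.DataFrame({
        "m1": [ids[i] for i in iu[sel]],
        "m2": [ids[j] for j in ju[sel]],
        "scope": scope_name,
        "n": cn[sel].astype(int),
        "n11": c11[sel].astype(int), "n12": c12[sel].astype(int),
        "n21": c21[sel].astype(int), "n22": c22[sel].astype(int),
        "D": D[sel], "Dprime": dprime[sel], "r2": r2[sel],
    })
    if with_p:
        df["p"] = fisher_p_column(df)
    return df


def fisher_p_column(pairs: pd.DataFrame) -> np.ndarray:
    """Two-sided Fisher p per row from the haplotype-count columns.

    Useful to defer p-value computation to the pair subset that actually
    needs it (e.g. same-group pairs entering the decay screen).
    """
    cache: dict[tuple, float] = {}
    tabs = pairs[["n11", "n12", "n21", "n22"]].to_numpy()
    ps = np.empty(len(pairs))
    for k in range(len(pairs)):
        key = tuple(tabs[k])
        if key not in cache:
            cache[key] = fisher_exact_2x2(tabs[k].reshape(2, 2))
        ps[k] = cache[key]
    return ps


def add_distances(pairs: pd.DataFrame, gmap: GeneticMap | None = None,
                  placements: Mapping[str, tuple[str, int]] | None = None
                  ) -> pd.DataFrame:
    """Attach genetic distance (cM, same linkage group) and physical distance
    (bp, same chromosome) columns; NaN where markers are unlinked."""
    df = pairs.copy()
    if gmap is not None:
        group_of, cm_of = {}, {}
        for g in gmap.groups:
            for m, cm in zip(g.markers, g.positions_cm):
                group_of[m] = g.name
                cm_of[m] = float(cm)
        same = [group_of.get(a) is not None and group_of.get(a) == group_of.get(b)
                for a, b in zip(df["m1"], df["m2"])]
        df["cm_dist"] = [abs(cm_of[a] - cm_of[b]) if s else np.nan
                         for a, b, s in zip(df["m1"], df["m2"], same)]
        df["linkage_group"] = [group_of.get(a) if s else None
                               for a, s in zip(df["m1"], same)]
    if placements is not None:
        df["bp_dist"] = [
            abs(placements[a][1] - placements[b][1])
            if (a in placements and b in placements
                and placements[a][0] == placements[b][0]) else np.nan
            for a, b in zip(df["m1"], df["m2"])]
        df["chrom"] = [
            placements[a][0]
            if (a in placements and b in placements
                and placements[a][0] == placements[b][0]) else None
            for a, b in zip(df["m1"], df["m2"])]
    return df


@dataclass
class LDDecayFit:
    scope: str
    distance_kind: str
    n_pairs: int
    model: str                       # "exponential" or "polynomial"
    params: np.ndarray
    f_pvalue: float | None
    threshold: float
    crossed: bool
    decay_distance: float            # NaN when the curve never crosses
    extrapolated: bool = False       # crossing beyond the observed range
    binned: pd.DataFrame = field(repr=False, default=None)

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.model == "exponential":
            a, b = self.params
            return a * np.exp(-b * d)
        return np.polyval(self.params, d)


def _exp_model(d, a, b):
    return a * np.exp(-b * d)


def ld_decay(pairs: pd.DataFrame, distance_col: str = "cm_dist",
             scope_name: str = "global", p_max: float | None = 0.001,
             threshold: float = 0.1, model: str = "auto",
             min_pairs: int = 10, n_bins: int = 10) -> LDDecayFit:
    """Fit the decay of r^2 with distance and locate the smallest distance at
    which the fitted curve drops to ``threshold``.

    Only pairs with a finite distance (same linkage group / chromosome) and,
    when a p column is present, p < ``p_max`` are used.  ``model`` is
    "polynomial", "exponential" or "auto" (exponential when an F-test against
    the constant model is significant at 0.05, else polynomial).  The
    exponential crossing is analytic and may lie beyond the observed range
    (``extrapolated``); polynomial crossings are only searched within the
    observed range, and a curve that never falls below the threshold yields
    the no-crossing sentinel (``crossed`` False, NaN distance).
    """
    df = pairs[np.isfinite(pairs[distance_col])]
    if p_max is not None and "p" in df.columns:
        df = df[df["p"] < p_max]
    if len(df) < min_pairs:
        raise ValueError(f"only {len(df)} qualifying pairs (< {min_pairs})")
    d = df[distance_col].to_numpy(dtype=float)
    y = df["r2"].to_numpy(dtype=float)

    exp_params, f_p = None, None
    if model in ("auto", "exponential"):
        try:
            p0 = (max(y.max(), 0.01), 1.0 / max(d.mean(), 1e-9))
            exp_params, _ = optimize.curve_fit(
                _exp_model, d, y, p0=p0,
                bounds=([0.0, 0.0], [1.5, np.inf]), maxfev=20000)
            rss1 = float(np.sum((y - _exp_model(d, *exp_params)) ** 2))
            rss0 = float(np.sum((y - y.mean()) ** 2))
            dof = len(y) - 2
            if dof > 0 and rss1 > 0:
                f_stat = (rss0 - rss1) / (rss1 / dof)
                f_p = float(stats.f.sf(f_stat, 1, dof))
            else:
                f_p = 0.0 if rss0 > rss1 else 1.0
        except RuntimeError:
            exp_params = None

    use_exp = (model == "exponential" and exp_params is not None) or (
        model == "auto" and exp_params is not None
        and f_p is not None and f_p < 0.05)
    if use_exp:
        chosen, params = "exponential", np.asarray(exp_params)
    else:
        chosen, params = "polynomial", np.polyfit(d, y, 2)

    fit = LDDecayFit(scope=scope_name, distance_kind=distance_col,
                     n_pairs=len(df), model=chosen, params=params,
                     f_pvalue=f_p, threshold=threshold, crossed=False,
                     decay_distance=float("nan"))
    if chosen == "exponential":
        a, b = params
        if a <= threshold:
            fit.crossed, fit.decay_distance = True, 0.0
        elif b > 0:
            root = float(np.log(a / threshold) / b)
            fit.crossed, fit.decay_distance = True, root
            fit.extrapolated = root > float(d.max())
    else:
        # first crossing within the observed distance range
        grid = np.linspace(0.0, float(d.max()), 4096)
        vals = fit.predict(grid)
        below = vals <= threshold
        if below[0]:
            fit.crossed, fit.decay_distance = True, 0.0
        elif below.any():
            k = int(np.argmax(below))
            root = optimize.brentq(lambda x: fit.predict(x) - threshold,
                                   grid[k - 1], grid[k])
            fit.crossed, fit.decay_distance = True, float(root)
    # binned means, for plotting / reporting only
    edges = np.linspace(0.0, float(d.max()), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    binned = pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "mean_r2": [y[which == b].mean() if np.any(which == b) else np.nan
                    for b in range(n_bins)],
        "n_pairs": [int(np.sum(which == b)) for b in range(n_bins)],
    })
    fit.binned = binned
    return fit


def ld_matrix(pairs: pd.DataFrame, ordered_markers: Sequence[str]
              ) -> pd.DataFrame:
    """Square matrix over map-ordered markers: r^2 in the upper triangle,
    p-values in the lower triangle, 1.0 on the diagonal."""
    ids = list(ordered_markers)
    pos = {m: i for i, m in enumerate(ids)}
    mat = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(mat, 1.0)
    has_p = "p" in pairs.columns
    for row in pairs.itertuples():
        if row.m1 not in pos or row.m2 not in pos:
            continue
        i, j = pos[row.m1], pos[row.m2]
        lo, hi = min(i, j), max(i, j)
        mat[lo, hi] = row.r2
        if has_p:
            mat[hi, lo] = row.p
    return pd.DataFrame(mat, index=ids, columns=ids)
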