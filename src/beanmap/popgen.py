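"""Per-marker diversity statistics and neutral-spectrum comparison.

Inbred lines are counted as single alleles; residual heterozygous calls are
excluded.  For a biallelic marker with minor/major frequencies p, q = 1 - p
over n sampled alleles:

    MAF  = min(p, q)
    PIC  = 1 - (p^2 + q^2) - 2 p^2 q^2
    pi   = n/(n-1) * 2pq          (per-site nucleotide diversity with the
                                   small-sample correction)

The folded site-frequency spectrum (SFS) is the histogram of MAF over
markers.  The neutral expectation is built from the standard constant-size
coalescent frequency spectrum — a derived allele is at count i in n samples
with probability proportional to 1/i — sampled ``reps`` times and folded,
which is equivalent in expectation to simulating genealogies for unlinked
sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CODE_A, CODE_B, GenotypeMatrix


def allele_stats(matrix: GenotypeMatrix, scope: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(n alleles, frequency of allele A) per marker within a line scope."""
    calls = matrix.calls if scope is None else matrix.calls[scope]
    nA = np.sum(calls == CODE_A, axis=0)
    nB = np.sum(calls == CODE_B, axis=0)
    n = nA + nB
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, nA / n, np.nan)
    return n, p


def pic(p):
    """Polymorphic information content of a biallelic locus."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - (p ** 2 + q ** 2) - 2.0 * p ** 2 * q ** 2


def pi_site(p, n):
    """Per-site nucleotide diversity with small-sample correction."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n / (n - 1.0) * 2.0 * p * (1.0 - p)
    return np.where(n >= 2, out, np.nan)


def maf(p):
    p = np.asarray(p, dtype=float)
    return np.minimum(p, 1.0 - p)


def marker_diversity(matrix: GenotypeMatrix, scope: np.ndarray | None = None,
                     scope_name: str = "global", min_n: int = 2) -> pd.DataFrame:
    """MAF / PIC / pi per marker within a scope.  Markers with fewer than
    ``min_n`` sampled alleles get NaN statistics (undefined sentinel)."""
    n, p = allele_stats(matrix, scope)
    ok = n >= min_n
    p = np.where(ok, p, np.nan)
    return pd.DataFrame({
        "marker": matrix.marker_ids,
        "scope": scope_name,
        "n": n,
        "maf": maf(p),
        "pic": pic(p),
        "pi": pi_site(p, n),
    })


def sfs_bin_edges(bins: int = 10) -> np.ndarray:
    return np.linspace(0.0, 0.5, bins + 1)


def folded_sfs(maf_values, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of MAF over markers on [0, 0.5] (monomorphic markers land in
    the first bin; NaNs are dropped)."""
    vals = np.asarray(maf_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    edges = sfs_bin_edges(bins)
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


def neutral_class_probs(n: int, folded: bool = True) -> np.ndarray:
    """Neutral frequency-spectrum class probabilities for n sampled alleles.

    Unfolded: P(count = i) proportional to 1/i over i = 1..n-1.  Folded:
    classes j = 1..floor(n/2) with P(j) proportional to 1/j + 1/(n-j)
    (halved when j = n - j).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    probs = (1.0 / i)
    probs /= probs.sum()
    if not folded:
        return probs
    k = n // 2
    out = np.zeros(k)
    for j in range(1, k + 1):
        out[j - 1] = probs[j - 1] + (probs[n - j - 1] if j != n - j else 0.0)
    return out


@dataclass
class SFSExpectation:
    n: int
    n_markers: int
    reps: int
    edges: np.ndarray
    mean: np.ndarray       # mean counts per bin across reps
    lo: np.ndarray         # 2.5 percentile
    hi: np.ndarray         # 97.5 percentile
    counts: np.ndarray     # (reps, bins) full simulation output


def neutral_sfs_expectation(n: int, n_markers: int, reps: int = 5000,
                            seed: int | None = None, bins: int = 10
                            ) -> SFSExpectation:
    """Simulated folded SFS under the Wright-Fisher neutral model.

    Each rep draws ``n_markers`` independent derived counts i in 1..n-1 with
    probability proportional to 1/i, folds them to MAF = min(i, n-i)/n and
    bins as :func:`folded_sfs` does.  Since markers are independent the
    per-rep bin counts follow a multinomial over bin probabilities, which is
    what is drawn.
    """
    rng = np.random.default_rng(seed)
    edges = sfs_bin_edges(bins)
    probs = neutral_class_probs(n, folded=False)
    i = np.arange(1, n)
    maf_i = np.minimum(i, n - i) / n
    # histogram semantics: right-open bins, last bin closed at 0.5
    bin_of = np.clip(np.digitize(maf_i, edges) - 1, 0, bins - 1)
    bin_probs = np.zeros(bins)
    np.add.at(bin_probs, bin_of, probs)
    counts = rng.multinomial(n_markers, bin_probs, size=reps)
    return SFSExpectation(
        n=n, n_markers=n_markers, reps=reps, edges=edges,
        mean=counts.mean(axis=0),
        lo=np.percentile(counts, 2.5, axis=0),
        hi=np.percentile(counts, 97.5, axis=0),
        counts=counts)


def neutrality_comparison(observed_counts, expectation: SFSExpectation
                          ) -> tuple[pd.DataFrame, bool]:
    """Per-bin deviation of an observed folded SFS from the neutral envelope.

    The expectation is rescaled to the observed total; z is the deviation in
    units of the envelope half-width.  The summary flag is True when every
    bin lies inside the (rescaled) 95% envelope.
    """
    obs = np.asarray(observed_counts, dtype=float)
    if obs.shape != expectation.mean.shape:
        raise ValueError("observed SFS binning does not match the expectation")
    total = obs.sum()
    scale = total / expectation.n_markers if expectation.n_markers else 1.0
    mean = expectation.mean * scale
    lo = expectation.lo * scale
    hi = expectation.hi * scale
    half = (hi - lo) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(half > 0, (obs - mean) / half,
                     np.where(obs == mean, 0.0, np.inf))
    table = pd.DataFrame({
        "bin_lo": expectation.edges[:-1], "bin_hi": expectation.edges[1:],
        "observed": obs, "expected_mean": mean, "lo": lo, "hi": hi, "z": z,
    })
    consistent = bool(np.all((obs >= lo - 1e-9) & (obs <= hi + 1e-9)))
    return table, consistent
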