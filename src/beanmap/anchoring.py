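"""Physical placement of markers from alignment hits.

Markers are placed at the midpoint of their lowest-E-value hit.  A marker is
a *singleton* when its best hit clears the E-value threshold and the next
best hit is at least ``separation``-fold weaker (E-values live on a log
scale, so the separation is multiplicative); otherwise it is *multiple*, or
*unplaced* when no hit clears the threshold.

For synthetic genomes a built-in ungapped seed-and-extend matcher stands in
for an external aligner.  It is deliberately simple: exact 11-mer seeds,
ungapped extension with blastn's default +2/−3 reward/penalty, and E-values
from the ungapped Karlin-Altschul statistics (lambda = 0.625, K = 0.41).
Real analyses should import tabular hits from a production aligner instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneModel, HitRecord
from .linkage import _round_half_up

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

LAMBDA_UNGAPPED = 0.625
K_UNGAPPED = 0.41
MATCH_SCORE = 2
MISMATCH_SCORE = -3


@dataclass(frozen=True)
class PlacementDecision:
    marker: str
    status: str                      # singleton | multiple | unplaced
    chrom: str | None
    position_bp: int | None          # midpoint of the best hit
    interval: tuple[int, int] | None
    strand: str | None
    best_evalue: float | None
    next_evalue: float | None


def _hit_sort_key(h: HitRecord):
    return (h.evalue, -h.bitscore, h.subject, h.start)


def classify_hits(marker: str, hits: Sequence[HitRecord],
                  e_threshold: float = 1e-30,
                  separation: float = 1e10) -> PlacementDecision:
    """Classify one marker's hits as singleton / multiple / unplaced."""
    hits = sorted(hits, key=_hit_sort_key)
    if not hits or hits[0].evalue > e_threshold:
        return PlacementDecision(marker, "unplaced", None, None, None, None,
                                 hits[0].evalue if hits else None, None)
    best = hits[0]
    next_e = hits[1].evalue if len(hits) > 1 else None
    if next_e is None:
        status = "singleton"
    elif best.evalue == 0.0:
        status = "singleton" if next_e > 0.0 else "multiple"
    else:
        status = "singleton" if next_e / best.evalue >= separation else "multiple"
    return PlacementDecision(marker, status, best.subject, best.midpoint,
                             (best.start, best.end), best.strand,
                             best.evalue, next_e)


def classify_all(hits: Iterable[HitRecord], marker_ids: Sequence[str],
                 e_threshold: float = 1e-30,
                 separation: float = 1e10) -> list[PlacementDecision]:
    by_marker: dict[str, list[HitRecord]] = {m: [] for m in marker_ids}
    for h in hits:
        by_marker.setdefault(h.query, []).append(h)
    return [classify_hits(m, by_marker.get(m, []), e_threshold, separation)
            for m in marker_ids]


def placement_summary(decisions: Sequence[PlacementDecision]) -> dict:
    """Counts and the singleton percentage (1 decimal)."""
    n = len(decisions)
    counts = {"singleton": 0, "multiple": 0, "unplaced": 0}
    for d in decisions:
        counts[d.status] += 1
    pct = _round_half_up(100.0 * counts["singleton"] / n, 1) if n else 0.0
    return {"n_total": n, "n_singleton": counts["singleton"],
            "n_multiple": counts["multiple"],
            "n_unplaced": counts["unplaced"], "singleton_pct": pct}


# -- built-in matcher ----------------------------------------------------------

def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, word: int) -> np.ndarray:
    """Integer codes of all words; words containing non-ACGT bases get -1."""
    if codes.size < word:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    c = np.where(valid, codes, 0).astype(np.int64)
    n_out = codes.size - word + 1
    out = np.zeros(n_out, dtype=np.int64)
    ok = np.ones(n_out, dtype=bool)
    for j in range(word):
        out += c[j:j + n_out] << (2 * (word - 1 - j))
        ok &= valid[j:j + n_out]
    return np.where(ok, out, -1)


class GenomeIndex:
    """Sorted k-mer index over a genome for repeated seed lookups."""

    def __init__(self, genome: Mapping[str, str], word: int = 11):
        self.word = word
        self.chroms: dict[str, np.ndarray] = {}
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in genome.items():
            codes = _encode(seq)
            self.chroms[name] = codes
            kmers = _kmer_codes(codes, word)
            order = np.argsort(kmers, kind="stable")
            self._sorted[name] = (kmers[order], order)
        self.total_length = int(sum(len(c) for c in self.chroms.values()))

    def seed_positions(self, chrom: str, code: int) -> np.ndarray:
        kmers, order = self._sorted[chrom]
        lo = np.searchsorted(kmers, code, side="left")
        hi = np.searchsorted(kmers, code, side="right")
        return order[lo:hi]


def _best_segment(scores: np.ndarray) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment (Kadane); returns (score, lo, hi)."""
    best, best_lo, best_hi = 0, 0, 0
    run, run_lo = 0, 0
    for i, s in enumerate(scores):
        if run <= 0:
            run, run_lo = int(s), i
        else:
            run += int(s)
        if run > best:
            best, best_lo, best_hi = run, run_lo, i + 1
    return best, best_lo, best_hi


def naive_search(query_id: str, query: str,
                 genome: Mapping[str, str] | GenomeIndex,
                 word: int = 11) -> list[HitRecord]:
    """Ungapped seed-and-extend search of one query against a genome.

    Both strands are searched; hits are the maximum-scoring ungapped segment
    on each seeded diagonal, with E = K * m * n * exp(-lambda * S).
    """
    if len(query) < word:
        raise ValueError(f"query shorter than word size {word}")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, word)
    m = len(query)
    hits: list[HitRecord] = []
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        qcodes = _encode(qseq)
        qkmers = _kmer_codes(qcodes, index.word)
        for chrom, gcodes in index.chroms.items():
            diagonals: set[int] = set()
            for qpos in range(len(qkmers)):
                code = qkmers[qpos]
                if code < 0:
                    continue
                for gpos in index.seed_positions(chrom, int(code)):
                    diagonals.add(int(gpos) - qpos)
            for diag in sorted(diagonals):
                g_lo = max(0, diag)
                g_hi = min(len(gcodes), diag + m)
                q_lo = g_lo - diag
                q_hi = g_hi - diag
                if q_hi <= q_lo:
                    continue
                qseg = qcodes[q_lo:q_hi]
                gseg = gcodes[g_lo:g_hi]
                match = (qseg == gseg) & (qseg >= 0)
                scores = np.where(match, MATCH_SCORE, MISMATCH_SCORE)
                score, lo, hi = _best_segment(scores)
                if score <= 0 or hi - lo < word:
                    continue
                n_match = int(match[lo:hi].sum())
                length = hi - lo
                evalue = (K_UNGAPPED * m * index.total_length
                          * exp(-LAMBDA_UNGAPPED * score))
                bitscore = (LAMBDA_UNGAPPED * score - log(K_UNGAPPED)) / log(2.0)
                s_start, s_end = g_lo + lo, g_lo + hi
                if strand == "+":
                    q_start, q_end = q_lo + lo, q_lo + hi
                else:
                    q_start, q_end = m - (q_lo + hi), m - (q_lo + lo)
                hits.append(HitRecord(
                    query=query_id, subject=chrom, start=s_start, end=s_end,
                    strand=strand, pident=100.0 * n_match / length,
                    length=length, mismatch=length - n_match, gapopen=0,
                    qstart=q_start, qend=q_end, evalue=evalue,
                    bitscore=bitscore))
    return sorted(hits, key=_hit_sort_key)


# -- marker/gene intersection --------------------------------------------------

def marker_gene_overlap(placements: Sequence[PlacementDecision],
                        genes: Sequence[GeneModel],
                        include_multiple: bool = False
                        ) -> list[tuple[str, str]]:
    """(marker, gene) pairs whose intervals share at least 1 bp (0-based
    half-open intersection).  A marker may match several genes and several
    markers may match the same gene."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = [g for g in genes if g.chrom == chrom]
        by_chrom[chrom] = (np.array([g.start for g in sub]),
                           np.array([g.end for g in sub]),
                           [g.gene_id for g in sub])
    statuses = {"singleton"} | ({"multiple"} if include_multiple else set())
    pairs: list[tuple[str, str]] = []
    for p in placements:
        if p.status not in statuses or p.chrom not in by_chrom:
            continue
        starts, ends, ids = by_chrom[p.chrom]
        s, e = p.interval
        for idx in np.flatnonzero((starts < e) & (ends > s)):
            pairs.append((p.marker, ids[idx]))
    return sorted(pairs)
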