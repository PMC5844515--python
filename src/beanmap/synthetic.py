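"""Synthetic genomes, RIL populations and structured diversity panels.

Everything downstream of genotyping is testable against these generators
because they record the generating truth: marker order, genetic positions,
per-interval meiotic recombination fractions, physical placements and
paralog insertions.

The crossover model is a Poisson process along the genetic scale (no
interference).  At marker resolution that is exactly equivalent to drawing
independent phase flips across adjacent marker intervals with probability
equal to the Haldane recombination fraction of each interval, which is how
meioses are simulated (vectorised across lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CODE_H, CODE_MISSING, GeneModel, GenotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class ChromosomeSpec:
    """One chromosome: length, marker positions and crossover landscape.

    ``intensity_breaks`` are bp boundaries (first 0, last = length) of the
    piecewise-constant meiotic intensity profile ``intensity`` in cM/Mb.
    ``pcenr`` optionally lists (start, end) bp intervals of suppressed
    recombination (informational truth for plateau detection).
    """

    name: str
    length_bp: int
    marker_positions: np.ndarray
    intensity_breaks: np.ndarray
    intensity: np.ndarray
    pcenr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.marker_positions = np.asarray(self.marker_positions, dtype=np.int64)
        self.intensity_breaks = np.asarray(self.intensity_breaks, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length must be > 0")
        pos = self.marker_positions
        if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 1
                         or pos[-1] > self.length_bp):
            raise ValueError(f"{self.name}: marker positions must be strictly "
                             f"increasing within [1, length]")
        if (self.intensity_breaks[0] != 0
                or self.intensity_breaks[-1] != self.length_bp
                or np.any(np.diff(self.intensity_breaks) <= 0)):
            raise ValueError(f"{self.name}: intensity breaks must span [0, length]")
        if len(self.intensity) != len(self.intensity_breaks) - 1:
            raise ValueError(f"{self.name}: need one intensity per interval")
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.name}: intensities must be >= 0")

    @property
    def _cum_cm(self) -> np.ndarray:
        seg_mb = np.diff(self.intensity_breaks) / 1e6
        return np.concatenate([[0.0], np.cumsum(seg_mb * self.intensity)])

    @property
    def total_cm(self) -> float:
        return float(self._cum_cm[-1])

    def genetic_pos(self, bp) -> np.ndarray:
        """Cumulative genetic position (cM) at physical position(s) bp."""
        return np.interp(np.asarray(bp, dtype=float),
                         self.intensity_breaks, self._cum_cm)

    def physical_pos(self, cm) -> np.ndarray:
        """Inverse of :meth:`genetic_pos` (piecewise-linear)."""
        return np.interp(np.asarray(cm, dtype=float),
                         self._cum_cm, self.intensity_breaks)

    @property
    def marker_cm(self) -> np.ndarray:
        return self.genetic_pos(self.marker_positions)


@dataclass
class GenomeSpec:
    chromosomes: list[ChromosomeSpec]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def n_markers(self) -> int:
        return int(sum(len(c.marker_positions) for c in self.chromosomes))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    def marker_table(self) -> pd.DataFrame:
        """Truth table: marker, chrom, bp, cM (in generating order)."""
        rows = []
        for c in self.chromosomes:
            cms = c.marker_cm
            for j, (bp, cm) in enumerate(zip(c.marker_positions, cms)):
                rows.append((f"{c.name}_m{j + 1:04d}", c.name, int(bp), float(cm)))
        return pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"])

    @property
    def total_cm(self) -> float:
        return float(sum(c.total_cm for c in self.chromosomes))

    @property
    def total_bp(self) -> int:
        return int(sum(c.length_bp for c in self.chromosomes))


def haldane_r(d_cm) -> np.ndarray:
    """Meiotic recombination fraction for a genetic distance under no
    interference: r = (1 - exp(-2 d_Morgan)) / 2."""
    d = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


# -- genome constructors ------------------------------------------------------

def _plateau_chromosome(name: str, length_bp: int, total_cm: float,
                        plateau: tuple[float, float] | None,
                        suppression: float) -> ChromosomeSpec:
    if plateau is None:
        breaks = np.array([0.0, length_bp])
        intens = np.array([total_cm / (length_bp / 1e6)])
        return ChromosomeSpec(name, length_bp, np.array([], dtype=np.int64),
                              breaks, intens)
    s, e = (int(round(plateau[0] * length_bp)),
            int(round(plateau[1] * length_bp)))
    arm_mb = (length_bp - (e - s)) / 1e6
    plat_mb = (e - s) / 1e6
    base = total_cm / (arm_mb + suppression * plat_mb)
    breaks, intens = [0.0], []
    if s > 0:
        breaks.append(s)
        intens.append(base)
    breaks.append(e)
    intens.append(base * suppression)
    if e < length_bp:
        breaks.append(length_bp)
        intens.append(base)
    return ChromosomeSpec(name, length_bp, np.array([], dtype=np.int64),
                          np.array(breaks), np.array(intens),
                          pcenr=[(s, e)])


def _place_markers(chrom: ChromosomeSpec, n: int, rng: np.random.Generator,
                   min_gap_bp: int = 200, end_pad_bp: int = 100) -> None:
    """Place n markers evenly on the genetic scale with jitter (gene-based
    markers sit in recombining euchromatin and are evenly distributed on the
    map, so genetic spacing is near-uniform and plateaus hold few markers)."""
    if n <= 0:
        return
    spacing = chrom.total_cm / (n + 1)
    cm = (np.arange(1, n + 1) + rng.uniform(-0.15, 0.15, size=n)) * spacing
    bp = np.round(chrom.physical_pos(cm)).astype(np.int64)
    bp = np.clip(bp, end_pad_bp, chrom.length_bp - end_pad_bp)
    # enforce strictly increasing positions with a minimum separation
    for j in range(1, n):
        if bp[j] < bp[j - 1] + min_gap_bp:
            bp[j] = bp[j - 1] + min_gap_bp
    if bp[-1] > chrom.length_bp - end_pad_bp:
        raise ValueError(f"{chrom.name}: cannot place {n} markers with "
                         f"min gap {min_gap_bp}")
    chrom.marker_positions = bp


# Reference-genome dimensions for the 11 common-bean chromosomes: physical
# lengths (Phytozome v1.0 pseudomolecules) and refined linkage-group lengths.
_PV_LENGTH_BP = [52159049, 49012014, 52266928, 45799695, 40676787, 31960678,
                 51729989, 59650056, 37463265, 43227687, 50184061]
_PV_LENGTH_CM = [147.0, 140.6, 114.4, 84.7, 82.8, 83.7, 108.3, 99.2, 46.5,
                 72.2, 67.5]
_PV_SNP_COUNT = [79, 93, 77, 22, 40, 78, 88, 84, 77, 27, 61]
# plateau extents as chromosome fractions; Pv9 is telocentric (terminal
# plateau), Pv6 has its low-recombination segment at 5-15 Mb
_PV_PLATEAU = [(0.30, 0.70)] * 5 + [(0.16, 0.47)] + [(0.30, 0.70)] * 2 + \
              [(0.00, 0.25)] + [(0.30, 0.70)] * 2

# published map totals; the printed totals row of the source map table is not
# the exact sum of its per-chromosome column, so both are kept
REFERENCE_TOTALS = {
    "initial_cm": 1762.5, "initial_markers": 981,
    "refined_cm": 1097.5, "refined_markers": 812,
    "bp": 514_130_209,
}


def reference_map_table() -> pd.DataFrame:
    """Published per-chromosome map dimensions for the 11 common-bean
    chromosomes: refined linkage-group length (cM) and pseudomolecule length
    (bp)."""
    return pd.DataFrame({
        "chrom": [f"Pv{i + 1:02d}" for i in range(11)],
        "cm": _PV_LENGTH_CM,
        "bp": _PV_LENGTH_BP,
    })


def default_genome(n_markers: int = 768, seed: int = 0,
                   suppression: float = 0.05,
                   allocation: str = "snp_counts") -> GenomeSpec:
    """An 11-chromosome genome emulating the common-bean reference: published
    chromosome lengths and linkage-group genetic lengths, pericentromeric
    plateaus with ``suppression``-fold reduced intensity, and gene-based
    markers allocated across chromosomes in the published proportions
    (``allocation="snp_counts"``) or proportional to genetic length
    (``allocation="map_length"``, giving near-uniform map spacing — the
    configuration used for parameter-recovery studies)."""
    rng = np.random.default_rng(seed)
    if allocation == "snp_counts":
        counts = np.array(_PV_SNP_COUNT, dtype=float)
    elif allocation == "map_length":
        counts = np.array(_PV_LENGTH_CM, dtype=float)
    else:
        raise ValueError("allocation must be 'snp_counts' or 'map_length'")
    alloc = np.floor(counts / counts.sum() * n_markers).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = counts / counts.sum() * n_markers - alloc
    for idx in np.argsort(-frac)[: n_markers - alloc.sum()]:
        alloc[idx] += 1
    chroms = []
    for i in range(11):
        c = _plateau_chromosome(f"Pv{i + 1:02d}", _PV_LENGTH_BP[i],
                                _PV_LENGTH_CM[i], _PV_PLATEAU[i], suppression)
        _place_markers(c, int(alloc[i]), rng)
        chroms.append(c)
    return GenomeSpec(chroms)


def scaled_genome(n_chromosomes: int = 3, chrom_length_bp: int = 6_000_000,
                  cm_per_chrom: float = 60.0, markers_per_chrom: int = 25,
                  plateau: tuple[float, float] | None = (0.30, 0.70),
                  suppression: float = 0.05, seed: int = 0) -> GenomeSpec:
    """A small genome for fast end-to-end runs; same structure as
    :func:`default_genome` but with configurable dimensions."""
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chromosomes):
        c = _plateau_chromosome(f"chr{i + 1:02d}", chrom_length_bp,
                                cm_per_chrom, plateau, suppression)
        _place_markers(c, markers_per_chrom, rng)
        chroms.append(c)
    return GenomeSpec(chroms)


# -- RIL population -----------------------------------------------------------

@dataclass
class RILConfig:
    """Selfing RIL design: two inbred parents, F1, then repeated selfing up
    to generation ``selfing_generations`` (F11 by default)."""

    n_lines: int = 80
    selfing_generations: int = 11
    missing_rate: float = 0.01
    het_rate: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.selfing_generations < 2:
            raise ValueError("selfing_generations must be >= 2")
        for name in ("missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class RILTruth:
    """Generating truth for a simulated RIL population."""

    marker_table: pd.DataFrame          # marker, chrom, bp, cM in true order
    adjacent_r: dict[str, np.ndarray]   # meiotic r between adjacent markers

    @property
    def placements(self) -> dict[str, tuple[str, int]]:
        return {row.marker: (row.chrom, int(row.bp))
                for row in self.marker_table.itertuples()}

    def chrom_markers(self, chrom: str) -> list[str]:
        sub = self.marker_table[self.marker_table["chrom"] == chrom]
        return list(sub["marker"])

    def meiotic_r(self, m1: str, m2: str) -> float:
        t = self.marker_table.set_index("marker")
        if t.loc[m1, "chrom"] != t.loc[m2, "chrom"]:
            return 0.5
        d = abs(t.loc[m1, "cM"] - t.loc[m2, "cM"])
        return float(haldane_r(d))


def _meiosis(h1: np.ndarray, h2: np.ndarray, r_adj: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per line from a diploid (h1, h2); phase flips between
    adjacent markers are Bernoulli(r) of the interval."""
    n, m = h1.shape
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    if m > 1:
        flips = (rng.random((n, m - 1)) < r_adj).astype(np.int8)
        phase = np.cumsum(np.concatenate([start, flips], axis=1), axis=1) % 2
    else:
        phase = start
    return np.where(phase == 0, h1, h2)


def simulate_ril_population(genome: GenomeSpec, cfg: RILConfig
                            ) -> tuple[GenotypeMatrix, RILTruth]:
    """Simulate an advanced-selfing RIL population genotyped at the genome's
    markers.  Returns the call matrix and the generating truth."""
    if genome.n_markers == 0:
        raise ValueError("genome has no markers")
    if cfg.seed is None:
        raise ValueError("RILConfig.seed is required for reproducibility")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_lines
    blocks = []
    adjacent_r: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        m = len(chrom.marker_positions)
        if m == 0:
            continue
        r_adj = haldane_r(np.diff(chrom.marker_cm))
        adjacent_r[chrom.name] = r_adj
        h1 = np.zeros((n, m), dtype=np.int8)
        h2 = np.ones((n, m), dtype=np.int8)
        for _ in range(cfg.selfing_generations - 1):
            g1 = _meiosis(h1, h2, r_adj, rng)
            g2 = _meiosis(h1, h2, r_adj, rng)
            h1, h2 = g1, g2
        calls = np.where(h1 == h2, h1.astype(np.int8), np.int8(CODE_H))
        blocks.append(calls)
    calls = np.concatenate(blocks, axis=1)
    # top up residual heterozygosity to the configured rate; the selfing
    # process itself leaves ~2^-(k-1) heterozygous cells
    natural = 2.0 ** -(cfg.selfing_generations - 1)
    extra = max(0.0, (cfg.het_rate - natural) / (1.0 - natural))
    if extra > 0:
        calls[(rng.random(calls.shape) < extra) & (calls != CODE_H)] = CODE_H
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = CODE_MISSING
    table = genome.marker_table()
    matrix = GenotypeMatrix(
        [f"RIL{i + 1:04d}" for i in range(n)], list(table["marker"]), calls)
    return matrix, RILTruth(table, adjacent_r)


# -- diversity panel ----------------------------------------------------------

@dataclass
class PanelConfig:
    """Two-genepool diversity panel with optional race substructure.

    ``divergence`` and ``drift`` are F-like parameters of a hierarchical
    Balding-Nichols drift model (0 = no differentiation).  Local LD within a
    race follows a latent AR(1) Gaussian-copula haplotype model: each inbred
    genotype thresholds a stationary Gaussian process whose correlation
    decays as exp(-d/ld_scale_bp) along the chromosome, so r^2 between
    nearby markers is high and decays exponentially while unlinked background
    LD comes only from the configured population structure.
    """

    pool_sizes: tuple[int, int] = (71, 115)
    pool_names: tuple[str, str] = ("Andean", "Mesoamerican")
    divergence: float = 0.3
    n_races: tuple[int, int] = (2, 4)
    drift: tuple[float, float] = (0.02, 0.4)
    ld_scale_bp: float = 10e6
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.pool_sizes) < 1:
            raise ValueError("pool sizes must be >= 1")
        for v in (self.divergence, *self.drift):
            if not 0.0 <= v < 1.0:
                raise ValueError("divergence/drift must be in [0, 1)")
        if self.ld_scale_bp <= 0:
            raise ValueError("ld_scale_bp must be > 0")


def _drift_freq(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw of derived allele frequencies at divergence f."""
    if f <= 0:
        return p.copy()
    scale = (1.0 - f) / f
    out = rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1 - p) * scale, 1e-9))
    return out


def simulate_diversity_panel(genome: GenomeSpec, cfg: PanelConfig
                             ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the structured diversity panel; returns the call matrix
    (labels attached) and a line -> (pool, race) table."""
    if genome.n_markers == 0:
        raise ValueError("genome has no markers")
    if cfg.seed is None:
        raise ValueError("PanelConfig.seed is required for reproducibility")
    rng = np.random.default_rng(cfg.seed)
    table = genome.marker_table()
    m_total = len(table)
    ancestral = rng.uniform(0.1, 0.9, size=m_total)

    chrom_slices: list[slice] = []
    adj_rho_parts: list[np.ndarray] = []
    off = 0
    for chrom in genome.chromosomes:
        m = len(chrom.marker_positions)
        chrom_slices.append(slice(off, off + m))
        gaps = np.diff(chrom.marker_positions).astype(float)
        adj_rho_parts.append(np.exp(-gaps / cfg.ld_scale_bp))
        off += m

    from scipy.stats import norm

    line_ids: list[str] = []
    call_blocks: list[np.ndarray] = []
    label_rows: list[tuple[str, str, str]] = []
    counter = 0
    for pool_idx, (size, pool) in enumerate(zip(cfg.pool_sizes, cfg.pool_names)):
        pool_freq = _drift_freq(ancestral, cfg.divergence, rng)
        n_races = cfg.n_races[pool_idx]
        race_freqs = [_drift_freq(pool_freq, cfg.drift[pool_idx], rng)
                      for _ in range(n_races)]
        race_of = rng.integers(0, n_races, size=size)
        calls_pool = np.empty((size, m_total), dtype=np.int8)
        for race in range(n_races):
            members = np.flatnonzero(race_of == race)
            if members.size == 0:
                continue
            # allele A iff the latent AR(1) Gaussian is below the race's
            # frequency threshold; correlation decays with physical distance
            thresh = norm.ppf(np.clip(race_freqs[race], 1e-6, 1 - 1e-6))
            z = np.empty((members.size, m_total))
            for sl, rho in zip(chrom_slices, adj_rho_parts):
                m = sl.stop - sl.start
                if m == 0:
                    continue
                zc = np.empty((members.size, m))
                zc[:, 0] = rng.standard_normal(members.size)
                eps = rng.standard_normal((members.size, max(m - 1, 1)))
                for j in range(m - 1):
                    zc[:, j + 1] = (rho[j] * zc[:, j]
                                    + np.sqrt(1.0 - rho[j] ** 2) * eps[:, j])
                z[:, sl] = zc
            calls_pool[members] = (z >= thresh).astype(np.int8)  # 0=A, 1=B
        for i in range(size):
            counter += 1
            line = f"G{counter:04d}"
            line_ids.append(line)
            label_rows.append((line, pool, f"{pool}_race{race_of[i] + 1}"))
        call_blocks.append(calls_pool)
    calls = np.concatenate(call_blocks, axis=0)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = CODE_MISSING
    labels = pd.DataFrame(label_rows, columns=["line", "pool", "race"]
                          ).set_index("line")
    matrix = GenotypeMatrix(line_ids, list(table["marker"]), calls,
                            labels=labels["pool"])
    return matrix, labels


# -- sequences and annotations ------------------------------------------------

def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def simulate_marker_sequences(genome: GenomeSpec, flank_len: int = 60,
                              n_paralogs: int = 0, seed: int | None = None,
                              paralog_divergence: float = 0.02
                              ) -> tuple[dict[str, str], dict[str, str],
                                         pd.DataFrame]:
    """Random chromosome sequences with each marker's (2*flank_len + 1) bp
    context at its truth position; ``n_paralogs`` markers get a slightly
    diverged second copy elsewhere to create multi-hit cases.

    Returns (chromosome seqs, marker flank seqs, paralog truth table).
    """
    if flank_len < 10:
        raise ValueError("flank_len must be >= 10")
    rng = np.random.default_rng(seed)
    ctx = 2 * flank_len + 1
    arrays: dict[str, np.ndarray] = {}
    flanks: dict[str, str] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    table = genome.marker_table()
    for chrom in genome.chromosomes:
        pos = chrom.marker_positions
        if pos.size:
            if pos[0] - 1 < flank_len or chrom.length_bp - pos[-1] < flank_len:
                raise ValueError(f"{chrom.name}: markers must be farther than "
                                 f"flank_len from chromosome ends")
            if np.any(np.diff(pos) <= 2 * flank_len):
                raise ValueError(f"{chrom.name}: marker contexts overlap")
        arrays[chrom.name] = _random_seq(chrom.length_bp, rng)
        occupied[chrom.name] = [(int(p) - 1 - flank_len, int(p) + flank_len)
                                for p in pos]
    for row in table.itertuples():
        s = row.bp - 1 - flank_len
        flanks[row.marker] = _decode(arrays[row.chrom][s:s + ctx])

    paralog_rows = []
    if n_paralogs:
        if n_paralogs > len(table):
            raise ValueError("n_paralogs exceeds marker count")
        chosen = rng.choice(len(table), size=n_paralogs, replace=False)
        names = [c.name for c in genome.chromosomes]
        for idx in sorted(chosen):
            row = table.iloc[int(idx)]
            copy = arrays[row.chrom][row.bp - 1 - flank_len:
                                     row.bp + flank_len].copy()
            n_mut = max(1, int(rng.binomial(ctx, paralog_divergence)))
            sites = rng.choice(ctx, size=n_mut, replace=False)
            copy[sites] = (copy[sites] + rng.integers(1, 4, size=n_mut)) % 4
            for _ in range(1000):
                tgt_chrom = names[rng.integers(len(names))]
                length = arrays[tgt_chrom].size
                start = int(rng.integers(flank_len, length - flank_len - ctx))
                iv = (start, start + ctx)
                if all(iv[1] <= a or iv[0] >= b for a, b in occupied[tgt_chrom]):
                    break
            else:  # pragma: no cover - genome essentially full
                raise ValueError("could not place paralog copy")
            arrays[tgt_chrom][iv[0]:iv[1]] = copy
            occupied[tgt_chrom].append(iv)
            paralog_rows.append((row.marker, tgt_chrom, iv[0] + flank_len + 1))
    chroms = {name: _decode(arr) for name, arr in arrays.items()}
    paralogs = pd.DataFrame(paralog_rows, columns=["marker", "chrom", "bp"])
    return chroms, flanks, paralogs


def simulate_gene_models(genome: GenomeSpec, genes_per_mb: float = 30.0,
                         mean_len: int = 3000, seed: int | None = None,
                         follow_intensity: bool = True) -> list[GeneModel]:
    """Random gene models; by default gene density follows the recombination
    intensity profile (gene-dense euchromatin recombines more)."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    for chrom in genome.chromosomes:
        n = int(round(chrom.length_bp / 1e6 * genes_per_mb))
        if follow_intensity and chrom.total_cm > 0:
            cm = rng.uniform(0, chrom.total_cm, size=n)
            starts = chrom.physical_pos(cm).astype(np.int64)
        else:
            starts = rng.integers(0, chrom.length_bp, size=n)
        starts = np.sort(starts)
        lengths = rng.integers(max(200, mean_len // 3), 2 * mean_len, size=n)
        for j, (s, ln) in enumerate(zip(starts, lengths)):
            e = min(int(s + ln), chrom.length_bp)
            if e <= s:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"{chrom.name}_g{j + 1:05d}", chrom.name,
                                   int(s), e, strand))
    return genes
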