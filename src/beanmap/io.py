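"""Readers, writers and core containers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  GFF3 and BLAST
tabular files (both 1-based inclusive) are converted at the boundary; BLAST
rows with subject start > end are recorded as minus-strand hits on the
normalised plus-strand interval.

Genotype calls are biallelic parent codes: ``A`` (first parent), ``B``
(second parent), ``H`` (heterozygous) and a configurable missing code
(default ``-``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# integer call codes used throughout the package
CODE_A, CODE_B, CODE_H, CODE_MISSING = 0, 1, 2, 3
_CALL_CHARS = np.array(["A", "B", "H", "-"])

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Lines x markers table of biallelic calls.

    ``calls`` is an int8 array with codes 0=A, 1=B, 2=H, 3=missing.
    ``labels`` optionally assigns a population label to each line.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    labels: pd.Series | None = None
    missing_code: str = "-"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            raise ValueError("call codes must be in {0 (A), 1 (B), 2 (H), 3 (missing)}")
        if self.labels is not None:
            self.labels = pd.Series(self.labels)
            missing = [l for l in self.line_ids if l not in self.labels.index]
            if missing:
                raise ValueError(f"labels missing for lines: {missing[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_ids.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def scope_mask(self, label: str | None = None) -> np.ndarray:
        """Boolean line mask for one population label (or all lines)."""
        if label is None:
            return np.ones(self.n_lines, dtype=bool)
        if self.labels is None:
            raise ValueError("matrix has no population labels")
        lab = self.labels.reindex(self.line_ids)
        return (lab == label).to_numpy()

    def call_strings(self) -> np.ndarray:
        out = _CALL_CHARS[self.calls]
        if self.missing_code != "-":
            out = np.where(self.calls == CODE_MISSING, self.missing_code, out)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.call_strings(), index=self.line_ids,
                            columns=self.marker_ids)

    def subset(self, lines: np.ndarray | None = None,
               markers: Sequence[str] | None = None) -> "GenotypeMatrix":
        calls = self.calls
        line_ids = self.line_ids
        if lines is not None:
            calls = calls[lines]
            line_ids = [l for l, keep in zip(self.line_ids, lines) if keep]
        if markers is not None:
            idx = [self.marker_index(m) for m in markers]
            calls = calls[:, idx]
            marker_ids = list(markers)
        else:
            marker_ids = list(self.marker_ids)
        labels = self.labels.loc[line_ids] if self.labels is not None else None
        return GenotypeMatrix(list(line_ids), marker_ids, calls.copy(),
                              labels=labels, missing_code=self.missing_code)


def _code_map(missing_code: str) -> dict[str, int]:
    return {"A": CODE_A, "B": CODE_B, "H": CODE_H, missing_code: CODE_MISSING}


def read_genotypes(path: str | Path, missing_code: str = "-") -> GenotypeMatrix:
    """Read a genotype TSV (header: marker ids; first column: line ids)."""
    codes = _code_map(missing_code)
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        marker_ids = header[1:]
        n_cols = len(header)
        line_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} fields, got {len(row)}"
                )
            line_ids.append(row[0])
            coded = []
            for col, cell in enumerate(row[1:]):
                try:
                    coded.append(codes[cell])
                except KeyError:
                    raise ParseError(
                        f"{path}: line {lineno} (line id {row[0]!r}), marker "
                        f"{marker_ids[col]!r}: invalid call {cell!r}"
                    ) from None
            rows.append(coded)
    calls = np.array(rows, dtype=np.int8).reshape(len(line_ids), len(marker_ids))
    return GenotypeMatrix(line_ids, marker_ids, calls, missing_code=missing_code)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["line", *matrix.marker_ids])
        for line_id, row in zip(matrix.line_ids, matrix.call_strings()):
            writer.writerow([line_id, *row])


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a line-label TSV (columns: line, pool[, race]) indexed by line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "line" not in df.columns or "pool" not in df.columns:
        raise ParseError(f"{path}: expected columns 'line' and 'pool'")
    return df.set_index("line")


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index_label="line")


# -- sequence / annotation / alignment formats -------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, stored 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end "
                             f"({self.start}, {self.end})")


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type(feature_type):
        genes.append(GeneModel(feat.id, feat.seqid, feat.start - 1, feat.end,
                               feat.strand or "+"))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbeanmap\t{feature_type}\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit; subject interval is 0-based half-open plus-strand."""

    query: str
    subject: str
    start: int
    end: int
    strand: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query}->{self.subject}: E-value must be >= 0")
        if not 0 <= self.start < self.end:
            raise ValueError(f"hit {self.query}->{self.subject}: bad interval")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Read 12-column tabular alignment hits (outfmt-6 dialect)."""
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                length = int(parts[3])
                mismatch = int(parts[4])
                gapopen = int(parts[5])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as err:
                raise ParseError(f"{path}: line {lineno}: {err}") from None
            strand = "+" if sstart <= send else "-"
            lo, hi = (sstart, send) if sstart <= send else (send, sstart)
            hits.append(HitRecord(
                query=parts[0], subject=parts[1], start=lo - 1, end=hi,
                strand=strand, pident=pident, length=length, mismatch=mismatch,
                gapopen=gapopen, qstart=min(qstart, qend) - 1,
                qend=max(qstart, qend), evalue=evalue, bitscore=bitscore,
            ))
    return hits


def write_blast_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.start + 1, h.end
            else:
                sstart, send = h.end, h.start + 1
            fh.write("\t".join(str(x) for x in (
                h.query, h.subject, f"{h.pident:.2f}", h.length, h.mismatch,
                h.gapopen, h.qstart + 1, h.qend, sstart, send,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            )) + "\n")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_map_tsv(map_frame: pd.DataFrame, path: str | Path) -> None:
    """Write a genetic map table (linkage_group, marker, cM, chromosome, bp)."""
    cols = ["linkage_group", "marker", "cM", "chromosome", "bp"]
    missing = [c for c in cols if c not in map_frame.columns]
    if missing:
        raise ValueError(f"map frame missing columns: {missing}")
    map_frame.to_csv(path, sep="\t", index=False, columns=cols)


def read_map_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"linkage_group": str, "marker": str,
                                            "chromosome": str})
    expected = {"linkage_group", "marker", "cM"}
    if not expected <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(expected)}")
    return df
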