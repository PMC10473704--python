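"""Shared genomic data model and text-format I/O.

All coordinates in the package are 0-based, half-open (BED convention).
1-based inputs are never auto-detected; readers take an explicit
``one_based`` flag that shifts starts on read.

Everywhere in the package a peak's "center" means its summit
(``start + summit_offset``); BED records without a summit column fall
back to the interval midpoint at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Malformed input file (carries the offending line number)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a model invariant."""


STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """ChIP-seq peak: an interval plus summit and enrichment metadata."""

    interval: GenomicInterval
    name: str
    summit_offset: int
    enrichment: float = 0.0
    qvalue: float = 0.0

    def __post_init__(self):
        if not (0 <= self.summit_offset < self.interval.length):
            raise ValidationError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )
        if self.enrichment < 0:
            raise ValidationError("enrichment must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute summit coordinate; the peak "center" package-wide."""
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """Gene body with a strand-aware transcription start site."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


class OccupancyTrack:
    """Per-base non-negative signal over a set of chromosomes."""

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite signal on {chrom}")
            if np.any(arr < 0):
                raise ValidationError(f"negative signal on {chrom}")
            self.data[chrom] = arr

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal over [start, end); positions outside the chromosome are 0."""
        arr = self.data[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        out = np.zeros(end - start, dtype=float)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def global_mean_sd(self) -> tuple[float, float]:
        allv = np.concatenate([v for v in self.data.values()]) if self.data else np.array([0.0])
        return float(allv.mean()), float(allv.std())


@dataclass
class CountMatrix:
    """Integer cell x gene expression counts with optional cluster labels."""

    counts: np.ndarray  # cells x genes
    cell_ids: list[str]
    gene_ids: list[str]
    clusters: dict[str, str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (cells x genes)")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"dimension mismatch: counts {self.counts.shape}, "
                f"{len(self.cell_ids)} cell ids, {len(self.gene_ids)} gene ids"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if self.clusters is not None:
            missing = set(self.cell_ids) - set(self.clusters)
            if missing:
                raise ValidationError(
                    f"cluster file missing {len(missing)} cells, e.g. "
                    f"{sorted(missing)[:3]}"
                )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None


# ---------------------------------------------------------------------------
# BED / narrowPeak


def _parse_bed_line(fields: list[str], lineno: int, one_based: bool) -> Peak:
    if len(fields) < 3:
        raise FormatError(f"line {lineno}: expected >= 3 BED columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer coordinates") from None
    if one_based:
        start -= 1
    if start >= end or start < 0:
        raise ValidationError(f"line {lineno}: invalid interval [{start}, {end})")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
    strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
    enrichment = 0.0
    qvalue = 0.0
    length = end - start
    summit_offset = length // 2
    if len(fields) >= 10:  # ENCODE narrowPeak
        try:
            enrichment = float(fields[6])
            qvalue = float(fields[8])
            summit = int(fields[9])
        except ValueError:
            raise FormatError(f"line {lineno}: malformed narrowPeak columns") from None
        if summit >= 0:
            summit_offset = summit
    return Peak(
        interval=GenomicInterval(chrom, start, end, strand),
        name=name,
        summit_offset=summit_offset,
        enrichment=enrichment,
        qvalue=qvalue,
    )


def read_bed(path: str | Path, one_based: bool = False) -> list[Peak]:
    """Read BED3/BED6/narrowPeak into Peaks, sorted by (chrom, start).

    narrowPeak column 10 populates the summit offset; plain BED records use
    the floor midpoint. Malformed lines raise :class:`FormatError` naming the
    line number; inverted intervals raise :class:`ValidationError`.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_bed_line(line.split("\t"), lineno, one_based))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return peaks


def write_bed(peaks: list[Peak], path: str | Path) -> None:
    """Write peaks as 10-column narrowPeak (round-trips the summit)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        "0",
                        p.interval.strand,
                        repr(p.enrichment),
                        "-1",
                        repr(p.qvalue),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / fixed-step WIG


def read_track(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> OccupancyTrack:
    """Read a bedGraph or fixed-step WIG file into an OccupancyTrack.

    Uncovered positions are 0. Overlapping bedGraph records and negative
    values are errors. ``chrom_sizes`` fixes array lengths; otherwise each
    chromosome extends to its last covered base.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    mode = "bedgraph"
    chrom, pos, step, span = None, 0, 1, 1
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            mode = "wig"
            kv = dict(tok.split("=") for tok in line.split()[1:])
            chrom = kv["chrom"]
            pos = int(kv["start"]) - 1  # WIG declarations are 1-based
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            continue
        fields = line.split()
        if mode == "wig":
            try:
                value = float(fields[0])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric WIG value") from None
            records.setdefault(chrom, []).append((pos, pos + span, value))
            pos += step
        else:
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed bedGraph record") from None
            if value < 0:
                raise ValidationError(f"line {lineno}: negative value {value}")
            if start >= end or start < 0:
                raise ValidationError(f"line {lineno}: invalid interval [{start}, {end})")
            records.setdefault(fields[0], []).append((start, end, value))

    data = {}
    for chrom, recs in records.items():
        size = chrom_sizes[chrom] if chrom_sizes else max(e for _, e, _ in recs)
        arr = np.zeros(size, dtype=float)
        covered = np.zeros(size, dtype=bool)
        for start, end, value in recs:
            if np.any(covered[start:end]):
                raise ValidationError(f"overlapping records on {chrom} at [{start}, {end})")
            covered[start:end] = True
            arr[start:end] = value
        data[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            data.setdefault(chrom, np.zeros(size, dtype=float))
    return OccupancyTrack(data)


def write_track(track: OccupancyTrack, path: str | Path) -> None:
    """Write as bedGraph, one record per constant run (zeros included)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(arr[s])!r}\n")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(
    matrix_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    clusters_path: str | Path | None = None,
) -> CountMatrix:
    """Read a MatrixMarket (genes x cells) or dense TSV (cells x genes)
    count matrix with one-name-per-line cell/gene files and an optional
    2-column (cell, cluster) TSV mapping every cell to one label."""
    cell_ids = _read_names(cells_path)
    gene_ids = _read_names(genes_path)
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(str(matrix_path))
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense()).T  # -> cells x genes
    else:
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0).to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("non-integer counts")
    counts = counts.astype(np.int64)
    clusters = read_clusters(clusters_path) if clusters_path else None
    return CountMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, clusters=clusters)


def read_clusters(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "cluster"], dtype=str)
    return dict(zip(df["cell"], df["cluster"]))


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_counts(
    m: CountMatrix,
    matrix_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    clusters_path: str | Path | None = None,
) -> None:
    """Write MatrixMarket (genes x cells) plus name and cluster files."""
    coo = scipy.sparse.coo_matrix(m.counts.T)
    scipy.io.mmwrite(str(matrix_path), coo, field="integer")
    Path(cells_path).write_text("".join(c + "\n" for c in m.cell_ids))
    Path(genes_path).write_text("".join(g + "\n" for g in m.gene_ids))
    if clusters_path is not None:
        if m.clusters is None:
            raise ValidationError("matrix has no cluster labels to write")
        with open(clusters_path, "w") as fh:
            for c in m.cell_ids:
                fh.write(f"{c}\t{m.clusters[c]}\n")


# ---------------------------------------------------------------------------
# gene tables and FASTA


def read_gene_table(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Minimal TSV gene input: gene_id, chrom, start, end, strand (header row)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"gene table missing columns {sorted(required - set(df.columns))}")
    genes = []
    for row in df.itertuples(index=False):
        start = int(row.start) - 1 if one_based else int(row.start)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                interval=GenomicInterval(row.chrom, start, int(row.end), row.strand),
            )
        )
    return genes


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into memory via a faidx index."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def check_chrom_names(peaks: list[Peak], available: set[str]) -> None:
    """Exact string match between peak and genome chromosome names; no
    normalization is attempted."""
    missing = sorted({p.chrom for p in peaks} - set(available))
    if missing:
        raise ValidationError(
            f"peak chromosomes absent from genome (exact-match policy): {missing}"
        )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
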