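"""Peak-to-gene annotation, overlap permutation testing, nucleosomal
classification, and metaprofiles.

Conventions: TSS distances are summit-based and signed, negative upstream
of the TSS on the gene's strand; the 3 kb assignment cutoff is inclusive.
The overlap null re-places each query peak uniformly on its own
chromosome preserving length (an exchangeable, deliberately conservative
null; no gap or blacklist model). Nucleosomal status is a transparent
threshold on mean summit-window occupancy, defaulting to the track-wide
mean + 1 SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    GeneModel,
    GenomicInterval,
    OccupancyTrack,
    Peak,
    ValidationError,
    warn,
)


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    gene_id: str | None
    distance_to_tss: int | None
    category: str  # overlapping | upstream | downstream | unassigned


@dataclass(frozen=True)
class OverlapTestResult:
    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_perm: int


@dataclass(frozen=True)
class NucClass:
    peak_id: str
    mean_occupancy: float
    label: str  # nucleosomal | non_nucleosomal


def _signed_tss_distance(summit: int, gene: GeneModel) -> int:
    if gene.interval.strand == "-":
        return gene.tss - summit
    return summit - gene.tss


def annotate_peaks(
    peaks: list[Peak], genes: list[GeneModel], max_dist: int = 3000
) -> list[PeakAnnotation]:
    """Assign each peak to a gene.

    A peak overlapping >= 1 gene body is 'overlapping' (nearest TSS among
    the overlapped genes); otherwise it goes to the gene with minimal
    |summit - TSS| when that distance is <= max_dist (inclusive). Ties
    break by smaller gene start, then lexicographic gene_id.
    """
    if not genes:
        raise ValidationError("gene list must be non-empty")
    out = []
    for p in peaks:
        on_chrom = [g for g in genes if g.interval.chrom == p.chrom]
        overlapped = [g for g in on_chrom if g.interval.overlaps(p.interval)]
        pool = overlapped if overlapped else on_chrom
        best = None
        for g in pool:
            d = _signed_tss_distance(p.summit, g)
            key = (abs(d), g.interval.start, g.gene_id)
            if best is None or key < best[0]:
                best = (key, g, d)
        if best is None:
            out.append(PeakAnnotation(p, None, None, "unassigned"))
            continue
        _, gene, dist = best
        if overlapped:
            out.append(PeakAnnotation(p, gene.gene_id, dist, "overlapping"))
        elif abs(dist) <= max_dist:
            category = "upstream" if dist < 0 else "downstream"
            out.append(PeakAnnotation(p, gene.gene_id, dist, category))
        else:
            out.append(PeakAnnotation(p, None, None, "unassigned"))
    return out


def annotation_table(annotations: list[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [a.peak.name for a in annotations],
            "chrom": [a.peak.chrom for a in annotations],
            "summit": [a.peak.summit for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "distance_to_tss": [a.distance_to_tss for a in annotations],
            "category": [a.category for a in annotations],
        }
    )


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not ivs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ivs = sorted(ivs)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _count_overlaps(starts: np.ndarray, lengths: np.ndarray,
                    b_starts: np.ndarray, b_ends: np.ndarray) -> np.ndarray:
    """Per-row count of intervals [starts, starts+lengths) intersecting any
    merged b interval; ``starts`` may be 2-D (perm x peak)."""
    if b_starts.size == 0:
        return np.zeros(starts.shape[:-1] if starts.ndim > 1 else (), dtype=int)
    idx = np.searchsorted(b_ends, starts, side="right")
    hit = (idx < len(b_starts)) & (np.take(b_starts, idx, mode="clip") < starts + lengths)
    return hit.sum(axis=-1)


def overlap_permutation_test(
    a: list[Peak],
    b: list[Peak],
    chrom_sizes: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Enrichment of interval overlap of peak set ``a`` with set ``b``.

    Observed statistic: number of peaks in ``a`` intersecting any interval
    of ``b``. Null: each peak of ``a`` independently re-placed uniformly on
    its own chromosome preserving its length. One-sided empirical p for
    enrichment: (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    b_by_chrom = {}
    for chrom in {p.chrom for p in b}:
        b_by_chrom[chrom] = _merge_intervals(
            [(p.start, p.end) for p in b if p.chrom == chrom]
        )
    observed = 0
    null_counts = np.zeros(n_perm, dtype=int)
    for chrom in sorted({p.chrom for p in a}):
        if chrom not in chrom_sizes:
            raise ValidationError(f"no size for chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        chrom_peaks = [p for p in a if p.chrom == chrom]
        lengths = np.array([p.interval.length for p in chrom_peaks])
        if np.any(lengths > size):
            raise ValidationError(f"peak longer than chromosome {chrom!r}")
        b_starts, b_ends = b_by_chrom.get(chrom, (np.empty(0, int), np.empty(0, int)))
        obs_starts = np.array([p.start for p in chrom_peaks])
        observed += int(_count_overlaps(obs_starts, lengths, b_starts, b_ends))
        rand_starts = rng.integers(0, size - lengths + 1,
                                   size=(n_perm, len(chrom_peaks)))
        null_counts += _count_overlaps(rand_starts, lengths, b_starts, b_ends)
    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (1 + int(np.sum(null_counts >= observed))) / (1 + n_perm)
    return OverlapTestResult(observed, null_mean, null_sd, z, p, n_perm)


def classify_nucleosomal(
    peaks: list[Peak],
    track: OccupancyTrack,
    window: int = 147,
    threshold: float | None = None,
) -> list[NucClass]:
    """Label peaks nucleosomal iff the mean occupancy over a ``window``-bp
    window centered on the summit is >= threshold (inclusive). Default
    threshold: track-wide mean + 1 SD. Windows past a chromosome end are
    truncated with a warning."""
    if threshold is None:
        mean, sd = track.global_mean_sd()
        threshold = mean + sd
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    out = []
    half = window // 2
    for p in peaks:
        if p.chrom not in track:
            raise ValidationError(f"track does not cover chromosome {p.chrom!r}")
        arr = track.chrom_values(p.chrom)
        lo, hi = p.summit - half, p.summit - half + window
        if lo < 0 or hi > len(arr):
            warn(f"occupancy window for {p.name} truncated at chromosome end")
            lo, hi = max(lo, 0), min(hi, len(arr))
        mean_occ = float(arr[lo:hi].mean())
        label = "nucleosomal" if mean_occ >= threshold else "non_nucleosomal"
        out.append(NucClass(peak_id=p.name, mean_occupancy=mean_occ, label=label))
    return out


def _anchor_profile(track: OccupancyTrack, anchor: GenomicInterval, flank: int,
                    n_bins: int, flank_bin_bp: int) -> np.ndarray:
    n_flank = flank // flank_bin_bp if flank > 0 else 0
    left = track.window_values(anchor.chrom, anchor.start - flank, anchor.start)
    body = track.window_values(anchor.chrom, anchor.start, anchor.end)
    right = track.window_values(anchor.chrom, anchor.end, anchor.end + flank)
    if anchor.strand == "-":
        left, body, right = right[::-1], body[::-1], left[::-1]

    def fixed_bins(v: np.ndarray) -> np.ndarray:
        if n_flank == 0:
            return np.empty(0)
        return v[: n_flank * flank_bin_bp].reshape(n_flank, flank_bin_bp).mean(axis=1)

    L = len(body)
    if L >= n_bins:
        edges = np.floor(np.linspace(0, L, n_bins + 1)).astype(int)
        body_bins = np.add.reduceat(body, edges[:-1]) / np.diff(edges)
    else:  # anchor shorter than the bin count: linear interpolation
        body_bins = np.interp(np.linspace(0, L - 1, n_bins), np.arange(L), body)
    return np.concatenate([fixed_bins(left), body_bins, fixed_bins(right)])


def metaprofile(
    track_numerator: OccupancyTrack,
    track_denominator: OccupancyTrack | None,
    anchors: list[GenomicInterval],
    flank: int = 0,
    n_bins: int = 50,
    flank_bin_bp: int = 50,
    epsilon: float = 1.0,
) -> np.ndarray:
    """Average signal profile over anchors scaled to ``n_bins`` body bins
    plus fixed-width flank bins. With a denominator the per-bin value is
    log2((num + eps) / (den + eps)), eps = 1 by default (recorded in
    pipeline output metadata). Minus-strand anchors are reversed before
    averaging."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if not anchors:
        raise ValidationError("anchors must be non-empty")
    num = np.mean(
        [_anchor_profile(track_numerator, a, flank, n_bins, flank_bin_bp) for a in anchors],
        axis=0,
    )
    if track_denominator is None:
        return num
    den = np.mean(
        [_anchor_profile(track_denominator, a, flank, n_bins, flank_bin_bp) for a in anchors],
        axis=0,
    )
    return np.log2((num + epsilon) / (den + epsilon))
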