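"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed): the same call
yields bit-identical output. Truth tables record everything a downstream
classifier needs to be scored without re-deriving generator internals.

Defaults encode the study conditions the pipeline is meant to emulate:
cell populations whose top 10% of genes carry 40-50% of transcripts,
peaks with G-box-like sites at constrained/relaxed/random inter-factor
spacings, 147 bp nucleosome footprints, and log2 LFQ tables with planted
bait-enriched proteins and low-abundance-biased dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CountMatrix, GenomicInterval, OccupancyTrack, Peak, ValidationError
from .motifs import ALPHABET, PWM, revcomp

NUCLEOSOME_BP = 147  # canonical core-particle footprint


@dataclass(frozen=True)
class ConcentrationSpec:
    """Two-level expression concentration: the top ``top_fraction`` of genes
    share ``mass_in_top`` of the per-cell transcript probability uniformly,
    the rest share the remainder uniformly. ``mass_in_top == top_fraction``
    is the homogeneous (all genes equal) case."""

    n_genes: int = 2000
    top_fraction: float = 0.10
    mass_in_top: float = 0.10
    total_counts_per_cell: int = 10000

    def __post_init__(self):
        if not 0 < self.top_fraction < 1:
            raise ValidationError("top_fraction must be in (0, 1)")
        if self.mass_in_top < self.top_fraction:
            raise ValidationError(
                "mass_in_top < top_fraction would invert the concentration"
            )
        if self.mass_in_top >= 1:
            raise ValidationError("mass_in_top must be < 1")
        if self.n_genes < 2 or self.total_counts_per_cell < 1:
            raise ValidationError("need n_genes >= 2 and positive totals")

    @property
    def n_top(self) -> int:
        return math.ceil(self.top_fraction * self.n_genes)

    def probabilities(self) -> np.ndarray:
        k, g = self.n_top, self.n_genes
        p = np.empty(g)
        if np.isclose(self.mass_in_top, self.top_fraction):
            p[:] = 1.0 / g
        else:
            p[:k] = self.mass_in_top / k
            p[k:] = (1 - self.mass_in_top) / (g - k)
        return p / p.sum()


@dataclass(frozen=True)
class SpacingTruth:
    """Planted inter-factor spacing regime.

    constrained: fixed offset with jitter sd <= 3 bp; relaxed: jitter in
    (3, 30]; random: second site uniform within the scan window."""

    mode: str
    offset: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.mode not in ("constrained", "relaxed", "random"):
            raise ValidationError(f"unknown spacing mode {self.mode!r}")
        if self.mode == "constrained" and self.jitter_sd > 3:
            raise ValidationError("constrained requires jitter_sd <= 3")
        if self.mode == "relaxed" and not (3 < self.jitter_sd <= 30):
            raise ValidationError("relaxed requires jitter_sd in (3, 30]")


@dataclass(frozen=True)
class LFQTruth:
    """Planted proteomics ground truth: which proteins are bait-enriched,
    by how much (log2 units), and the missing-not-at-random dropout rate."""

    enriched_ids: frozenset
    effect: float
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.effect <= 0:
            raise ValidationError("effect must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")


def gen_counts(
    spec: ConcentrationSpec,
    n_cells: int,
    seed: int,
    cluster_label: str = "sim",
    cell_prefix: str = "cell",
) -> CountMatrix:
    """Multinomial cell x gene counts under a two-level probability vector."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(spec.total_counts_per_cell, spec.probabilities(),
                             size=n_cells)
    cell_ids = [f"{cell_prefix}_{i:05d}" for i in range(n_cells)]
    gene_ids = [f"gene_{j:05d}" for j in range(spec.n_genes)]
    return CountMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        clusters={c: cluster_label for c in cell_ids},
    )


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.length)]
    return "".join(ALPHABET[i] for i in cols)


def gen_genome_with_peaks(
    n_peaks: int,
    peak_len: int,
    motif_a: PWM,
    motif_b: PWM,
    truth: SpacingTruth,
    seed: int,
    window: int = 50,
    chrom: str = "chrSim",
) -> tuple[dict[str, str], list[Peak], pd.DataFrame]:
    """One uniform-ACGT chromosome of ``n_peaks`` abutting peaks.

    Each peak carries one PWM-sampled site of ``motif_a`` centered on the
    summit and one site of ``motif_b`` at offset + Normal(0, jitter_sd)
    (constrained/relaxed) or uniform within +/- window (random), either
    strand. The site table records planted positions, strands and
    summit-relative center offsets."""
    need = 2 * (motif_a.length + motif_b.length + abs(truth.offset)
                + math.ceil(6 * truth.jitter_sd))
    if peak_len < need:
        raise ValidationError(f"peak_len {peak_len} < required {need}")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(ALPHABET), size=n_peaks * peak_len)
    peaks, rows = [], []
    for i in range(n_peaks):
        start = i * peak_len
        summit = start + peak_len // 2
        name = f"peak_{i:05d}"
        for factor, pwm in (("a", motif_a), ("b", motif_b)):
            if factor == "a":
                center = summit
            elif truth.mode == "random":
                center = summit + int(rng.integers(-window, window + 1))
            else:
                center = summit + truth.offset + int(
                    round(rng.normal(0, truth.jitter_sd))
                )
                if truth.mode == "constrained" and abs(center - summit) > window:
                    raise ValidationError(
                        f"planted site at {center - summit:+d} bp falls outside the "
                        f"+/-{window} bp scan window in constrained mode"
                    )
            site = _sample_site(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else revcomp(site)
            s0 = center - pwm.length // 2
            seq[s0 : s0 + pwm.length] = list(inserted)
            rows.append(
                {"peak_id": name, "factor": factor, "start": s0, "strand": strand,
                 "center": s0 + pwm.length // 2,
                 "offset": s0 + pwm.length // 2 - summit, "site": site}
            )
        peaks.append(
            Peak(interval=GenomicInterval(chrom, start, start + peak_len),
                 name=name, summit_offset=peak_len // 2)
        )
    genome = {chrom: "".join(seq)}
    site_table = pd.DataFrame(rows)
    return genome, peaks, site_table


def gen_occupancy(
    peaks: list[Peak],
    nucleosomal_ids: set[str],
    amp: float,
    seed: int,
    chrom_sizes: dict[str, int],
    footprint: int = NUCLEOSOME_BP,
) -> OccupancyTrack:
    """Folded-normal noise |N(0, amp/10)| everywhere; nucleosomal peaks add a
    ``footprint``-bp plateau of height ``amp`` centered on the summit."""
    if amp <= 0:
        raise ValidationError("amp must be > 0")
    rng = np.random.default_rng(seed)
    data = {c: np.abs(rng.normal(0, amp / 10, size=n)) for c, n in chrom_sizes.items()}
    half = footprint // 2
    for p in peaks:
        if p.name in nucleosomal_ids:
            lo = max(p.summit - half, 0)
            hi = min(p.summit - half + footprint, chrom_sizes[p.chrom])
            data[p.chrom][lo:hi] += amp
    return OccupancyTrack(data)


def gen_lfq(
    n_proteins: int,
    design: dict[str, str],
    truth: LFQTruth,
    seed: int,
    bait_group: str | None = None,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    rep_noise_sd: float = 0.5,
    missing_quantile: float = 0.25,
):
    """Log2 LFQ table (proteins x samples) with planted enrichment.

    Per-protein abundances are Normal(base_mean, base_sd) shared across
    samples, with replicate noise sd ``rep_noise_sd``; enriched proteins are
    shifted +effect in the bait group. Values below the matrix-wide
    ``missing_quantile`` quantile drop out with probability
    ``missing_rate`` (missing-not-at-random at low abundance)."""
    from .plms import LFQTable  # deferred: plms owns the table type

    groups: dict[str, list[str]] = {}
    for sample, group in design.items():
        groups.setdefault(group, []).append(sample)
    for group, samples in groups.items():
        if len(samples) < 2:
            raise ValidationError(f"group {group!r} has < 2 replicates")
    if bait_group is None:
        bait_group = next(iter(groups))
    if bait_group not in groups:
        raise ValidationError(f"bait_group {bait_group!r} not in design")
    rng = np.random.default_rng(seed)
    samples = list(design)
    protein_ids = [f"prot_{i:04d}" for i in range(n_proteins)]
    unknown = set(truth.enriched_ids) - set(protein_ids)
    if unknown:
        raise ValidationError(f"enriched ids not generated: {sorted(unknown)[:3]}")
    base = rng.normal(base_mean, base_sd, size=n_proteins)
    values = base[:, None] + rng.normal(0, rep_noise_sd, size=(n_proteins, len(samples)))
    enriched_mask = np.array([p in truth.enriched_ids for p in protein_ids])
    bait_cols = np.array([design[s] == bait_group for s in samples])
    values[np.ix_(enriched_mask, bait_cols)] += truth.effect
    if truth.missing_rate > 0:
        cutoff = np.quantile(values, missing_quantile)
        dropout = (values < cutoff) & (rng.random(values.shape) < truth.missing_rate)
        values = np.where(dropout, np.nan, values)
    df = pd.DataFrame(values, index=protein_ids, columns=samples)
    design_df = pd.DataFrame({"group": [design[s] for s in samples]}, index=samples)
    return LFQTable(values=df, design=design_df, ms_ms_identified=set(protein_ids))
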