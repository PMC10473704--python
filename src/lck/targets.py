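"""TF target-gene calling: cluster-restricted expression criteria combined
with peak-to-gene binding.

A gene is a target of a TF iff, among the cells expressing that TF, it is
expressed in at least ``min_expr_fraction`` of them (default 25%), its
log2 fold change versus the remaining cells is at least ``min_log2fc``
(default 0.223, ~log2 of a 1.17-fold change), and it has at least one
binding site of the TF within ``max_peak_gene_dist`` of its TSS or body.
All thresholds are inclusive. Fold changes are computed on per-10k
normalized means with pseudocount 1, the standard single-cell marker
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountMatrix, ValidationError


@dataclass(frozen=True)
class TargetRule:
    min_expr_fraction: float = 0.25
    min_log2fc: float = 0.223
    require_bound: bool = True
    max_peak_gene_dist: int = 3000

    def __post_init__(self):
        if not 0 < self.min_expr_fraction <= 1:
            raise ValidationError("min_expr_fraction must be in (0, 1]")
        if self.min_log2fc < 0:
            raise ValidationError("min_log2fc must be >= 0")


def tf_positive_cells(m: CountMatrix, tf_gene: str, min_count: int = 1) -> set[str]:
    """Cells with count(tf_gene) >= min_count ("cells that express the TF")."""
    j = m.gene_index(tf_gene)
    mask = m.counts[:, j] >= min_count
    return {c for c, keep in zip(m.cell_ids, mask) if keep}


def expression_stats(
    m: CountMatrix,
    cells_in: set[str],
    cells_out: set[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene expressed fraction in the in-group and log2 fold change of
    per-10k normalized mean expression (in vs out, pseudocounted)."""
    if not cells_in or not cells_out:
        raise ValidationError("both cell groups must be non-empty")
    if cells_in & cells_out:
        raise ValidationError("cell groups must be disjoint")
    idx = {c: i for i, c in enumerate(m.cell_ids)}
    rows_in = np.array(sorted(idx[c] for c in cells_in))
    rows_out = np.array(sorted(idx[c] for c in cells_out))
    counts = m.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals[np.concatenate([rows_in, rows_out])] == 0):
        raise ValidationError("zero-count cell in a comparison group")
    cpm = counts * 1e4 / totals  # per-10k normalization
    frac_in = (counts[rows_in] >= 1).mean(axis=0)
    mean_in = cpm[rows_in].mean(axis=0)
    mean_out = cpm[rows_out].mean(axis=0)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    return pd.DataFrame(
        {"gene_id": m.gene_ids, "expr_fraction_in": frac_in, "log2fc": log2fc}
    )


def call_targets(
    stats: pd.DataFrame, bound_genes: set[str], rule: TargetRule = TargetRule()
) -> pd.DataFrame:
    """Apply the target rule; thresholds are inclusive ("at least")."""
    df = stats.copy()
    df["bound"] = df["gene_id"].isin(bound_genes)
    expr_ok = df["expr_fraction_in"] >= rule.min_expr_fraction
    fc_ok = df["log2fc"] >= rule.min_log2fc
    bound_ok = df["bound"] if rule.require_bound else True
    df["is_target"] = expr_ok & fc_ok & bound_ok
    return df


def bound_genes_from_annotation(annotation: pd.DataFrame) -> set[str]:
    """Genes with >= 1 assigned binding site in an annotation table."""
    assigned = annotation[annotation["category"] != "unassigned"]
    return set(assigned["gene_id"].dropna())
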