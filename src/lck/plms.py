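"""Proximity-labeling proteomics enrichment statistics.

The pipeline mirrors the standard label-free workflow: log2 LFQ values
with missing-not-at-random dropout are imputed from a downshifted normal
fitted to the whole matrix; an optional bait normalization subtracts the
bait (biotin ligase fusion) intensity per sample; enrichment per contrast
is scored with an S0-moderated two-sample t statistic,
t = (mean_a - mean_b) / (SE_pooled + s0), whose s0 = 0 limit is exactly
the pooled Student t; significance uses a plug-in permutation FDR with
threshold monotonization. A final multi-control filter intersects the
per-contrast significant sets with detection and MS/MS-evidence gates.

The permutation null excludes the identity label assignment and its
complement: both reproduce the observed |t| exactly and would otherwise
floor the estimated FDR at 2 / n_perm regardless of effect size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import ValidationError, warn

MAX_EXHAUSTIVE = 10000  # use all distinct assignments when there are this few


@dataclass
class LFQTable:
    """proteins x samples log2 intensities (NaN = missing), a design table
    (indexed by sample, with at least a 'group' column), and the set of
    MS/MS-identified proteins."""

    values: pd.DataFrame
    design: pd.DataFrame
    ms_ms_identified: set[str] = field(default_factory=set)

    def __post_init__(self):
        if {"line", "treatment"}.issubset(self.design.columns) and "group" not in self.design.columns:
            self.design = self.design.assign(
                group=self.design["line"] + "_" + self.design["treatment"]
            )
        if "group" not in self.design.columns:
            raise ValidationError("design needs a 'group' column (or line+treatment)")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValidationError(f"samples without design entry: {sorted(missing)}")

    def group_samples(self, group: str) -> list[str]:
        samples = [s for s in self.values.columns if self.design.loc[s, "group"] == group]
        if not samples:
            raise ValidationError(f"no samples in group {group!r}")
        return samples

    def detected_counts(self, group: str) -> pd.Series:
        """Per-protein count of non-missing values within a group."""
        return self.values[self.group_samples(group)].notna().sum(axis=1)


@dataclass(frozen=True)
class EnrichParams:
    s0: float = 0.5
    fdr: float = 0.05
    n_perm: int = 250
    impute_width: float = 0.3  # SDs
    impute_downshift: float = 1.8  # SDs
    min_reps_detected: int = 2

    def __post_init__(self):
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")
        if not 0 < self.fdr < 1:
            raise ValidationError("fdr must be in (0, 1)")


def impute_missing(t: LFQTable, params: EnrichParams, seed: int) -> LFQTable:
    """Fill missing values with draws from Normal(mu - downshift * sigma,
    (width * sigma)^2), mu and sigma from the observed total matrix
    ("total matrix mode"). Observed entries are untouched."""
    vals = t.values.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size == 0:
        raise ValidationError("all-missing matrix")
    if observed.size < 100:
        raise ValidationError("need >= 100 observed values to estimate matrix moments")
    mu, sigma = observed.mean(), observed.std(ddof=0)
    rng = np.random.default_rng(seed)
    mask = np.isnan(vals)
    draws = rng.normal(mu - params.impute_downshift * sigma,
                       params.impute_width * sigma, size=int(mask.sum()))
    out = vals.copy()
    out[mask] = draws
    return LFQTable(
        values=pd.DataFrame(out, index=t.values.index, columns=t.values.columns),
        design=t.design.copy(),
        ms_ms_identified=set(t.ms_ms_identified),
    )


def normalize_to_bait(t: LFQTable, bait_protein: str) -> LFQTable:
    """Subtract the bait's log2 value from every protein, per sample (the
    bait row becomes 0 everywhere)."""
    if bait_protein not in t.values.index:
        raise ValidationError(f"bait {bait_protein!r} not in table")
    bait = t.values.loc[bait_protein]
    bad = [s for s in t.values.columns if pd.isna(bait[s])]
    if bad:
        raise ValidationError(f"bait missing in sample(s): {bad}")
    return LFQTable(
        values=t.values.sub(bait, axis=1),
        design=t.design.copy(),
        ms_ms_identified=set(t.ms_ms_identified),
    )


def moderated_t(group_a, group_b, s0: float = 0.5) -> tuple[float, float]:
    """S0-moderated two-sample statistic: (diff, diff / (SE_pooled + s0)).

    SE_pooled is the pooled-variance two-sample standard error, so s0 = 0
    recovers Student's t exactly.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    diff = float(a.mean() - b.mean())
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    if se + s0 == 0:
        raise ValidationError("zero variance in both groups with s0=0: t undefined")
    return diff, diff / (se + s0)


def _t_matrix(values: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray,
              s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moderated t over a matrix (vectorized moderated_t)."""
    a, b = values[:, cols_a], values[:, cols_b]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    return diff, diff / (se + s0)


def _label_assignments(n: int, na: int, n_perm: int, seed: int):
    """Index sets for pseudo-group A. Exhaustive (all distinct choices,
    excluding the identity assignment and its complement) when few enough;
    otherwise seeded random draws."""
    identity = tuple(range(na))
    complement = tuple(range(na, n))
    total = math.comb(n, na)
    if total <= max(MAX_EXHAUSTIVE, 0):
        combos = [c for c in itertools.combinations(range(n), na)
                  if c != identity and c != complement]
        return combos, True
    rng = np.random.default_rng(seed)
    combos = []
    while len(combos) < n_perm:
        c = tuple(sorted(rng.choice(n, size=na, replace=False)))
        if c != identity and c != complement:
            combos.append(c)
    return combos, False


def permutation_fdr(
    t: LFQTable,
    contrast: tuple[str, str],
    params: EnrichParams = EnrichParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-protein enrichment for contrast (group_a, group_b).

    Observed |t_mod| per protein; the null recomputes the matrix-wide
    moderated t under random label assignments. A protein's plug-in FDR at
    its own |t| threshold is (mean null count of |t| >= threshold) /
    (observed count >= threshold); estimates are monotonized from the top
    so the significant set is a |t|-threshold set. Columns: protein, diff,
    t_mod, fdr_est, passed.
    """
    ga, gb = contrast
    cols_a = [t.values.columns.get_loc(s) for s in t.group_samples(ga)]
    cols_b = [t.values.columns.get_loc(s) for s in t.group_samples(gb)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("group sizes must be >= 2")
    values = t.values.to_numpy(dtype=float)
    if np.isnan(values[:, cols_a + cols_b]).any():
        raise ValidationError("missing values present: impute before testing")
    sub = values[:, cols_a + cols_b]
    na, n = len(cols_a), len(cols_a) + len(cols_b)
    diff, t_obs = _t_matrix(sub, np.arange(na), np.arange(na, n), params.s0)
    abs_obs = np.abs(t_obs)

    assignments, exhaustive = _label_assignments(n, na, params.n_perm, seed)
    if not exhaustive and len(assignments) < params.n_perm:
        warn(f"only {len(assignments)} distinct permutations available")
    null_values = []
    all_idx = np.arange(n)
    for combo in assignments:
        ia = np.array(combo)
        ib = np.setdiff1d(all_idx, ia)
        _, t_null = _t_matrix(sub, ia, ib, params.s0)
        null_values.append(np.abs(t_null))
    null_flat = np.sort(np.concatenate(null_values))
    n_perm_used = len(assignments)

    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    # smoothed mean null count >= threshold: add-one in the spirit of the
    # never-zero permutation p-value rule, so a finite permutation set
    # cannot report an estimated FDR of exactly 0
    null_ge = len(null_flat) - np.searchsorted(null_flat, sorted_abs, side="left")
    obs_ge = np.arange(1, len(sorted_abs) + 1)
    fdr_raw = ((null_ge + 1) / (n_perm_used + 1)) / obs_ge
    fdr_mono = np.minimum.accumulate(fdr_raw[::-1])[::-1]  # threshold set
    fdr_est = np.empty_like(fdr_mono)
    fdr_est[order] = fdr_mono
    return pd.DataFrame(
        {
            "protein": t.values.index,
            "diff": diff,
            "t_mod": t_obs,
            "fdr_est": fdr_est,
            "passed": fdr_est <= params.fdr,
        }
    )


def read_lfq(values_path, design_path, msms_path=None) -> LFQTable:
    """values: TSV proteins x samples (first column = protein id);
    design: TSV with columns sample, group (plus any extras);
    msms: optional one-protein-per-line evidence list (default: all)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    if msms_path is not None:
        with open(msms_path) as fh:
            msms = {ln.strip() for ln in fh if ln.strip()}
    else:
        msms = set(values.index)
    return LFQTable(values=values, design=design, ms_ms_identified=msms)


def write_lfq(t: LFQTable, values_path, design_path, msms_path=None) -> None:
    t.values.to_csv(values_path, sep="\t", index_label="protein")
    t.design.to_csv(design_path, sep="\t", index_label="sample")
    if msms_path is not None:
        with open(msms_path, "w") as fh:
            for p in sorted(t.ms_ms_identified):
                fh.write(p + "\n")


def candidate_filter(
    results_by_contrast: dict[str, pd.DataFrame],
    t: LFQTable,
    params: EnrichParams,
    bait_biotin_group: str,
    raw: LFQTable | None = None,
) -> set[str]:
    """High-confidence candidates: enriched in every configured contrast,
    detected in >= min_reps_detected replicates of the biotin-treated bait
    group (on the pre-imputation table if given), and MS/MS-identified."""
    if not results_by_contrast:
        raise ValidationError("no contrasts configured")
    passed = None
    for name, res in results_by_contrast.items():
        # only positive (bait-enriched) direction counts
        s = set(res.loc[res["passed"] & (res["diff"] > 0), "protein"])
        passed = s if passed is None else passed & s
    detection_table = raw if raw is not None else t
    detected = detection_table.detected_counts(bait_biotin_group)
    well_detected = set(detected[detected >= params.min_reps_detected].index)
    return passed & well_detected & set(t.ms_ms_identified)
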