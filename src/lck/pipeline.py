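"""End-to-end orchestration: a validated YAML config drives the six
pipeline stages (entropy; annotate -> nuc_classify -> motif_spacing;
targets; plms), each writing TSV/JSON outputs with a sidecar metadata
JSON naming its parameters and derived seed.

A single global seed deterministically derives per-stage seeds via a
stage-name CRC, so any stage is reproducible in isolation and a full run
is byte-identical for a fixed config + seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import entropy as entropy_mod
from . import io_core, motifs, peaks as peaks_mod, plms, spacing, synthetic, targets

STAGES = ("entropy", "annotate", "nuc_classify", "motif_spacing", "targets", "plms")

_KNOWN_TOP = {"version", "seed", "outdir", "inputs", "params"}
_KNOWN_INPUTS = {
    "counts_mtx", "counts_cells", "counts_genes", "counts_clusters",
    "genome_fasta", "peaks_bed", "genes_tsv", "occupancy_bedgraph",
    "motifs_meme", "lfq_tsv", "lfq_design_tsv",
}
_KNOWN_PARAMS = {
    "tf_gene", "spacing_window", "spacing_pair", "nuc_window", "nuc_threshold",
    "min_expr_fraction", "min_log2fc", "max_peak_gene_dist",
    "s0", "fdr_primary", "fdr_secondary", "n_perm",
    "bait_group", "control_group", "mock_group",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    inputs: dict[str, Path]
    params: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = Path(path).parent
        unknown = set(doc) - _KNOWN_TOP
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if doc.get("version") != 1:
            raise ConfigError("config 'version' must be 1")
        inputs_doc = doc.get("inputs", {})
        unknown = set(inputs_doc) - _KNOWN_INPUTS
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        inputs = {}
        for key, rel in inputs_doc.items():
            p = (base / rel).resolve()
            if not p.exists():
                raise ConfigError(f"input {key}: path does not exist: {p}")
            inputs[key] = p
        params = doc.get("params", {})
        unknown = set(params) - _KNOWN_PARAMS
        if unknown:
            raise ConfigError(f"unknown param keys: {sorted(unknown)}")
        outdir = (base / doc.get("outdir", "out")).resolve()
        return cls(seed=int(doc["seed"]), outdir=outdir, inputs=inputs, params=params)


def stage_seed(global_seed: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2**31)


def _write_meta(path: Path, stage: str, seed: int, params: dict) -> None:
    meta = {"stage": stage, "seed": seed, "params": params, "lck_version": __version__}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1, default=str) + "\n"
    )


def _write_table(df: pd.DataFrame, path: Path, stage: str, seed: int, params: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    _write_meta(path, stage, seed, params)


def run_pipeline(config: RunConfig) -> dict:
    """Execute configured stages in dependency order; returns (and writes)
    a machine-readable run report. A failed stage is reported and its
    dependents are skipped."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    report: dict = {"seed": config.seed, "lck_version": __version__, "stages": []}
    state: dict = {}

    def record(stage, status, outputs=(), error=None):
        report["stages"].append(
            {"stage": stage, "status": status,
             "outputs": sorted(Path(o).name for o in outputs),
             "seed": stage_seed(config.seed, stage), "error": error}
        )

    def run_stage(stage, deps, fn):
        failed = {s["stage"] for s in report["stages"] if s["status"] != "ok"}
        if any(d in failed for d in deps):
            record(stage, "skipped")
            return
        try:
            outputs = fn(stage_seed(config.seed, stage))
            record(stage, "ok", outputs)
        except Exception as exc:  # noqa: BLE001 - report and continue
            record(stage, "failed", error=f"{type(exc).__name__}: {exc}")

    # --- entropy -----------------------------------------------------------
    def do_entropy(seed):
        m = io_core.read_counts(
            config.inputs["counts_mtx"], config.inputs["counts_cells"],
            config.inputs["counts_genes"], config.inputs.get("counts_clusters"),
        )
        per_cell, summary = entropy_mod.entropy_by_cluster(m)
        f1, f2 = out / "entropy_per_cell.tsv", out / "entropy_by_cluster.tsv"
        meta = {"min_count": 1, "log_base": "e (nats)"}
        _write_table(per_cell, f1, "entropy", seed, meta)
        _write_table(summary, f2, "entropy", seed, meta)
        state["counts"] = m
        return [f1, f2]

    # --- annotate ----------------------------------------------------------
    def do_annotate(seed):
        pk = io_core.read_bed(config.inputs["peaks_bed"])
        genes = io_core.read_gene_table(config.inputs["genes_tsv"])
        max_dist = int(p.get("max_peak_gene_dist", 3000))
        ann = peaks_mod.annotate_peaks(pk, genes, max_dist=max_dist)
        table = peaks_mod.annotation_table(ann)
        f = out / "peak_annotation.tsv"
        _write_table(table, f, "annotate", seed, {"max_dist": max_dist})
        state["peaks"] = pk
        state["annotation"] = table
        return [f]

    # --- nuc_classify ------------------------------------------------------
    def do_nuc(seed):
        track = io_core.read_track(config.inputs["occupancy_bedgraph"])
        window = int(p.get("nuc_window", 147))
        threshold = p.get("nuc_threshold")
        classes = peaks_mod.classify_nucleosomal(
            state["peaks"], track, window=window,
            threshold=None if threshold is None else float(threshold),
        )
        df = pd.DataFrame(
            {"peak_id": [c.peak_id for c in classes],
             "mean_occupancy": [c.mean_occupancy for c in classes],
             "label": [c.label for c in classes]}
        )
        f = out / "nucleosomal_classes.tsv"
        _write_table(df, f, "nuc_classify", seed,
                     {"window": window, "threshold": threshold or "mean+1sd"})
        state["nuc_classes"] = df
        return [f]

    # --- motif_spacing -----------------------------------------------------
    def do_motif_spacing(seed):
        genome = io_core.read_fasta(config.inputs["genome_fasta"])
        io_core.check_chrom_names(state["peaks"], set(genome))
        pwms = motifs.read_meme(config.inputs["motifs_meme"])
        if len(pwms) < 2:
            raise io_core.ValidationError("need >= 2 motifs for spacing")
        pwm_a, pwm_b = pwms[0], pwms[1]
        window = int(p.get("spacing_window", 50))
        nuc = dict(zip(state["nuc_classes"]["peak_id"], state["nuc_classes"]["label"]))
        subsets = {
            "nucleosomal": [q for q in state["peaks"] if nuc.get(q.name) == "nucleosomal"],
            "non_nucleosomal": [q for q in state["peaks"]
                                if nuc.get(q.name) == "non_nucleosomal"],
        }
        presence = motifs.motif_presence(subsets, pwm_a, genome, window=window)
        f1 = out / "motif_presence.tsv"
        _write_table(presence, f1, "motif_spacing", seed,
                     {"window": window, "motif": pwm_a.name,
                      "min_score": "0.8*consensus"})
        hits_a, hits_b = [], []
        for q in state["peaks"]:
            ha = motifs.best_hit_near_center(pwm_a, q, genome, window=window)
            hb = motifs.best_hit_near_center(pwm_b, q, genome, window=window)
            if ha:
                hits_a.append(ha)
            if hb:
                hits_b.append(hb)
        pair = p.get("spacing_pair", f"{pwm_b.name}-{pwm_a.name}")
        dist = spacing.shared_peak_distances(hits_a, hits_b, pair_name=pair)
        ddf = pd.DataFrame({"distance_bp": dist.distances})
        f2 = out / "spacing_distances.tsv"
        meta = {"window": window, "pair": pair,
                "convention": "signed, hit-midpoint minus hit-midpoint",
                "n_shared_peaks": dist.n_shared_peaks}
        _write_table(ddf, f2, "motif_spacing", seed, meta)
        call = spacing.classify_spacing(dist, window=window, null_halfwidth=window)
        f3 = out / "spacing_call.json"
        f3.write_text(json.dumps(
            {"pair_name": call.pair_name, "call": call.call, "spread_bp": call.spread,
             "uniformity_p": call.uniformity_p, "n": call.n,
             "null": "uniform(-window, window); first factor summit-anchored"},
            sort_keys=True, indent=1) + "\n")
        _write_meta(f3, "motif_spacing", seed, meta)
        return [f1, f2, f3]

    # --- targets -----------------------------------------------------------
    def do_targets(seed):
        m = state["counts"]
        tf_gene = p.get("tf_gene") or m.gene_ids[0]
        cells_in = targets.tf_positive_cells(m, tf_gene)
        cells_out = set(m.cell_ids) - cells_in
        stats = targets.expression_stats(m, cells_in, cells_out)
        rule = targets.TargetRule(
            min_expr_fraction=float(p.get("min_expr_fraction", 0.25)),
            min_log2fc=float(p.get("min_log2fc", 0.223)),
            max_peak_gene_dist=int(p.get("max_peak_gene_dist", 3000)),
        )
        bound = targets.bound_genes_from_annotation(state["annotation"])
        calls = targets.call_targets(stats, bound, rule)
        f = out / "target_calls.tsv"
        _write_table(calls, f, "targets", seed,
                     {"tf_gene": tf_gene, "rule": rule.__dict__,
                      "out_group": "all TF-negative cells"})
        return [f]

    # --- plms --------------------------------------------------------------
    def do_plms(seed):
        table = plms.read_lfq(config.inputs["lfq_tsv"], config.inputs["lfq_design_tsv"])
        bait = p.get("bait_group", "bait_biotin")
        control = p.get("control_group", "wt_biotin")
        mock = p.get("mock_group", "bait_mock")
        params1 = plms.EnrichParams(
            s0=float(p.get("s0", 0.5)), fdr=float(p.get("fdr_primary", 0.05)),
            n_perm=int(p.get("n_perm", 250)),
        )
        params2 = plms.EnrichParams(s0=params1.s0, fdr=float(p.get("fdr_secondary", 0.1)),
                                    n_perm=params1.n_perm)
        imputed = plms.impute_missing(table, params1, seed)
        results = {
            "bait_vs_control": plms.permutation_fdr(imputed, (bait, control), params1,
                                                    seed=seed + 1),
            "bait_vs_mock": plms.permutation_fdr(imputed, (bait, mock), params2,
                                                 seed=seed + 2),
        }
        files = []
        for name, res in results.items():
            f = out / f"plms_{name}.tsv"
            fdr = params1.fdr if name == "bait_vs_control" else params2.fdr
            _write_table(res, f, "plms", seed,
                         {"contrast": name, "s0": params1.s0, "fdr": fdr,
                          "n_perm": params1.n_perm,
                          "imputation": {"width_sd": params1.impute_width,
                                         "downshift_sd": params1.impute_downshift,
                                         "mode": "total matrix"}})
            files.append(f)
        candidates = plms.candidate_filter(results, imputed, params1,
                                           bait_biotin_group=bait, raw=table)
        f = out / "plms_candidates.txt"
        f.write_text("".join(c + "\n" for c in sorted(candidates)))
        _write_meta(f, "plms", seed, {"gates": ["all contrasts", ">=2 bait reps",
                                                "MS/MS identified"]})
        files.append(f)
        return files

    run_stage("entropy", (), do_entropy)
    run_stage("annotate", (), do_annotate)
    run_stage("nuc_classify", ("annotate",), do_nuc)
    run_stage("motif_spacing", ("annotate", "nuc_classify"), do_motif_spacing)
    run_stage("targets", ("entropy", "annotate"), do_targets)
    run_stage("plms", (), do_plms)

    report["n_stages"] = len(report["stages"])
    report["ok"] = all(s["status"] == "ok" for s in report["stages"])
    (out / "run_report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1) + "\n"
    )
    return report


# ---------------------------------------------------------------------------
# demo fixtures


def make_demo(outdir: str | Path, seed: int = 7) -> Path:
    """Write a complete small synthetic dataset plus a run.yaml driving the
    full pipeline; returns the config path. Truth tables for every
    classifier stage are written alongside the inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)

    # counts: one homogeneous and one concentrated population, plus a TF
    # expressed only in the concentrated cluster.
    spec_hom = synthetic.ConcentrationSpec(n_genes=300, mass_in_top=0.10,
                                           total_counts_per_cell=3000)
    spec_con = synthetic.ConcentrationSpec(n_genes=300, mass_in_top=0.50,
                                           total_counts_per_cell=3000)
    m1 = synthetic.gen_counts(spec_hom, 80, seed=rng_seed, cluster_label="uniform",
                              cell_prefix="u")
    m2 = synthetic.gen_counts(spec_con, 80, seed=rng_seed + 1,
                              cluster_label="concentrated", cell_prefix="c")
    counts = np.vstack([m1.counts, m2.counts])
    # gene_00000 acts as the TF marker: concentrated cells only
    counts[: len(m1.cell_ids), 0] = 0
    counts[len(m1.cell_ids):, 0] += 5
    m = io_core.CountMatrix(
        counts=counts,
        cell_ids=m1.cell_ids + m2.cell_ids,
        gene_ids=m1.gene_ids,
        clusters={**m1.clusters, **m2.clusters},
    )
    io_core.write_counts(m, outdir / "counts.mtx", outdir / "cells.txt",
                         outdir / "genes.txt", outdir / "clusters.tsv")

    # genome + peaks with planted constrained co-binding sites
    gbox = motifs.build_pwm(["CACGTG"] * 20, pseudocount=0.1, name="GBOX")
    boxb = motifs.build_pwm(["TGACTCAT"] * 20, pseudocount=0.1, name="BOXB")
    truth = synthetic.SpacingTruth(mode="constrained", offset=8, jitter_sd=1.0)
    genome, pk, site_table = synthetic.gen_genome_with_peaks(
        n_peaks=120, peak_len=240, motif_a=gbox, motif_b=boxb, truth=truth,
        seed=rng_seed + 2,
    )
    io_core.write_fasta(genome, outdir / "genome.fa")
    io_core.write_bed(pk, outdir / "peaks.narrowPeak")
    site_table.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    motifs.write_meme([gbox, boxb], outdir / "motifs.meme")

    # gene models: one gene per peak, TSS near the summit
    genes = []
    chrom = pk[0].chrom
    size = len(genome[chrom])
    for i, q in enumerate(pk):
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start = min(q.summit + 20 + (i % 5) * 100, size - 40)
            iv = io_core.GenomicInterval(chrom, start, min(start + 30, size), strand)
        else:
            end = max(q.summit - 20 - (i % 5) * 100, 40)
            iv = io_core.GenomicInterval(chrom, max(end - 30, 0), end, strand)
        genes.append(io_core.GeneModel(gene_id=m.gene_ids[i % len(m.gene_ids)], interval=iv))
    # deduplicate gene ids keeping first occurrence
    seen, uniq = set(), []
    for g in genes:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            uniq.append(g)
    io_core.write_gene_table(uniq, outdir / "genes.tsv")

    # occupancy: alternate peaks nucleosomal
    nucleosomal = {q.name for i, q in enumerate(pk) if i % 2 == 0}
    track = synthetic.gen_occupancy(pk, nucleosomal, amp=10.0, seed=rng_seed + 3,
                                    chrom_sizes={chrom: size})
    io_core.write_track(track, outdir / "occupancy.bedGraph")
    pd.DataFrame(
        {"peak_id": [q.name for q in pk],
         "nucleosomal": [q.name in nucleosomal for q in pk]}
    ).to_csv(outdir / "truth_nucleosomal.tsv", sep="\t", index=False)

    # LFQ with planted enrichment
    enriched = frozenset(f"prot_{i:04d}" for i in range(20))
    design = {}
    for grp, n in (("bait_biotin", 3), ("wt_biotin", 3), ("bait_mock", 3)):
        for r in range(1, n + 1):
            design[f"{grp}_r{r}"] = grp
    lfq = synthetic.gen_lfq(
        n_proteins=300, design=design,
        truth=synthetic.LFQTruth(enriched_ids=enriched, effect=3.0, missing_rate=0.2),
        seed=rng_seed + 4, bait_group="bait_biotin",
    )
    plms.write_lfq(lfq, outdir / "lfq.tsv", outdir / "lfq_design.tsv")
    pd.DataFrame({"protein": sorted(enriched)}).to_csv(
        outdir / "truth_enriched.tsv", sep="\t", index=False
    )

    config = {
        "version": 1,
        "seed": int(seed),
        "outdir": "out",
        "inputs": {
            "counts_mtx": "counts.mtx",
            "counts_cells": "cells.txt",
            "counts_genes": "genes.txt",
            "counts_clusters": "clusters.tsv",
            "genome_fasta": "genome.fa",
            "peaks_bed": "peaks.narrowPeak",
            "genes_tsv": "genes.tsv",
            "occupancy_bedgraph": "occupancy.bedGraph",
            "motifs_meme": "motifs.meme",
            "lfq_tsv": "lfq.tsv",
            "lfq_design_tsv": "lfq_design.tsv",
        },
        "params": {
            "tf_gene": "gene_00000",
            "spacing_window": 50,
            "bait_group": "bait_biotin",
            "control_group": "wt_biotin",
            "mock_group": "bait_mock",
            "n_perm": 250,
        },
    }
    config_path = outdir / "run.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
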