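# lck — lineage chromatin kit

`lck` is an analysis toolkit for studying how transcription factors and
chromatin state interact during cell-fate commitment, built around the
kind of multi-omic evidence used in stomatal-lineage work in
*Arabidopsis*: single-cell RNA-seq, ChIP-seq of the stage-specific bHLH
factors and their chromatin-remodeler partners, MNase-seq nucleosome
occupancy, and TurboID proximity-labeling proteomics. It is aimed at
computational biologists who want transparent, testable re-implementations
of the bespoke statistics these studies rely on, plus synthetic-data
generators that plant ground truth for every downstream classifier.

## What it computes

- **Transcriptional entropy** (`lck.entropy`). Per-cell Shannon entropy
  S = −Σᵢ pᵢ ln pᵢ with pᵢ = cᵢ/Σc over a cell's gene counts, in nats; a
  proxy for differentiation potential. Includes the two-level
  concentration model (top 10% of genes carrying 40–50% of transcripts),
  its closed-form entropy, and the exact finite-depth expectation of the
  plug-in estimator for oracle comparisons.
- **Peak integration** (`lck.peaks`). Summit-based peak→gene annotation
  with an inclusive 3 kb TSS cutoff; peak-set overlap testing against a
  uniform re-placement permutation null with empirical p
  = (1 + #{null ≥ obs})/(1 + n_perm); nucleosomal vs non-nucleosomal
  classification by mean occupancy in a 147 bp summit window; scaled
  metaprofiles of log₂(ChIP/Input).
- **Motifs** (`lck.motifs`). PWM estimation with pseudocounts, both-strand
  log₂-odds scanning, best-hit search with the hit midpoint constrained to
  ±50 bp of the summit, and motif-presence/stringency comparison between
  peak subsets.
- **Spacing** (`lck.spacing`). Signed center-to-center distances between
  two factors' binding sites at shared peaks, a from-first-principles
  two-sample Kolmogorov–Smirnov test (D exact, asymptotic p), and the
  constrained / relaxed / random co-binding classification.
- **Targets** (`lck.targets`). The target-gene rule: expressed in ≥ 25% of
  TF-positive cells, log₂ fold change ≥ 0.223 (per-10k normalized,
  pseudocount 1), and ≥ 1 binding site near the gene.
- **PL-MS enrichment** (`lck.plms`). Downshifted-normal imputation
  (total-matrix mode), bait normalization, the S0-moderated t statistic
  t = Δ/(SE_pooled + s0) with s0 = 0.5, permutation-based FDR with
  threshold monotonization, and the multi-control high-confidence filter.
- **Synthetic data** (`lck.synthetic`). Deterministic, seeded generators
  for all of the above with planted truth tables.

## Worked example

Generate a small synthetic dataset and run all six pipeline stages:

```bash
lck demo --out demo --seed 7
lck run --config demo/run.yaml
```

This prints `entropy: ok … plms: ok` for the six stages and writes TSV/JSON
outputs (each with a `.meta.json` sidecar recording parameters and the
derived stage seed) under `demo/out/`. With seed 7:

- `entropy_by_cluster.tsv` — the uniform-expression cluster has median
  entropy 5.650 nats versus 5.144 for the cluster whose top 10% of genes
  carry 50% of transcripts, at an equal number of expressed genes
  (~299): concentrating transcript mass lowers entropy without changing
  gene detection.
- `spacing_call.json` — the planted 8 bp co-binding offset (jitter sd
  1 bp) is called `"constrained"` with robust spread 1.48 bp and
  uniformity p ≈ 1.2e-22 against the non-coordinated (flat) reference.
- `plms_candidates.txt` — exactly the 20 planted bait-enriched proteins
  pass both contrasts (vs control at FDR 0.05, vs mock at FDR 0.1), the
  ≥ 2-replicate detection gate and the MS/MS gate.
- `target_calls.tsv` — e.g. `gene_00001` is a target (expressed in 100% of
  TF⁺ cells, log₂FC 2.28, bound), while unbound or non-enriched genes are
  not.

Each `lck` subcommand (`entropy`, `annotate`, `overlap-test`,
`nuc-classify`, `metaprofile`, `pwm-build`, `scan`, `motif-presence`,
`spacing`, `targets`, `plms`, `simulate …`) exposes the same operations on
user-supplied files; see `lck --help`.

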