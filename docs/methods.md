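# Methods

This note documents the models and statistics `lck` implements, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the package's known limitations.

## Coordinates and data model

All intervals are 0-based, half-open (BED convention); 1-based inputs are
shifted only when a reader is told so explicitly (`one_based=True` /
`--one-based`) — conventions are never guessed. A peak's *center* always
means its summit (`start + summit_offset`); BED records without a summit
column fall back to the floor midpoint at read time. Chromosome names are
matched exactly; a peak/genome name mismatch raises an error listing the
disjoint names rather than attempting `chr`-prefix normalization.

## Transcriptional entropy

Per cell, S = −Σᵢ pᵢ ln pᵢ with pᵢ = cᵢ/Σc summed over genes with cᵢ > 0
(0·ln 0 := 0). Natural log: entropy is reported in nats, and every
ordering the package relies on is invariant to the log base (a display
conversion is available). No pseudocounts and no library-size
normalization enter the computation — pᵢ is a within-cell proportion, so
depth normalization would cancel anyway. "Expressed" means raw count ≥
min_count (default 1).

The concentration model is a two-level probability vector: the top
k = ⌈f·G⌉ genes share mass m uniformly, the remaining G−k genes share
1−m uniformly (m = f is the homogeneous case). Its asymptotic entropy is

    S* = −[ m ln(m/k) + (1−m) ln((1−m)/(G−k)) ].

At finite sequencing depth N the plug-in estimator is biased low by
≈ (K−1)/(2N) (≈ 0.1 nats at G = 2000, N = 10⁴), which is far larger than
the Monte Carlo error of a mean over a few hundred cells. Simulated means
are therefore compared to the *exact* finite-depth expectation

    E[Ŝ] = ln N − (1/N) Σᵢ E[cᵢ ln cᵢ],

computed from the binomial marginals of the multinomial
(`expected_plugin_entropy`); S* is exposed as the infinite-depth limit.
Generator defaults — 2,000 genes and 10,000 counts per cell — are typical
plant scRNA-seq scales; both are free parameters.

## Peak → gene annotation

A peak overlapping ≥ 1 gene body is assigned to the overlapped gene
(category `overlapping`); otherwise to the gene minimizing |summit − TSS|
when that distance is ≤ 3 kb, *inclusive* at exactly 3000 ("at least"/
"within" thresholds are inclusive package-wide). Distances are signed,
negative upstream of the TSS on the gene's strand. Ties break by smaller
gene start, then lexicographic gene id, making annotation
input-order-invariant.

## Overlap permutation test

Observed statistic: the number of query peaks intersecting any interval
of the reference set. Null: each query peak is independently re-placed
uniformly on its own chromosome, preserving length. This is the simplest
exchangeable null; it ignores mappability gaps and blacklists and is
therefore conservative for genomes where peaks concentrate in accessible
sequence. The empirical enrichment p is (1 + #{null ≥ obs})/(1 + n_perm),
never exactly zero; z is reported against the null mean and SD.
Default n_perm = 1000.

## Nucleosomal classification

A peak is nucleosomal iff mean occupancy over a 147 bp window (the core
particle footprint; mononucleosome gels run at ~150 bp) centered on the
summit is ≥ threshold, inclusive at equality. The default threshold is
the track-wide mean + 1 SD. This deliberately replaces opaque
nucleosome-caller output with a transparent, single-parameter rule: the
scientific claim being tested is about *relative* occupancy at binding
sites, and the rule must be auditable and scoreable against planted
truth. Windows extending past a chromosome end are truncated with a
warning.

## Metaprofiles

Anchors are scaled to n_bins body bins (mean per bin; anchors shorter
than the bin count use linear interpolation) plus fixed-width flank bins;
minus-strand anchors are reversed before averaging. With an input track
as denominator, the per-bin value is log₂((num+ε)/(den+ε)) with ε = 1 to
avoid −∞; ε is recorded in output metadata.

## Motif scanning

PWMs are column-stochastic 4×L matrices estimated as
(count + pseudocount)/(N + 4·pseudocount), default pseudocount 0.5;
zero-probability entries (pseudocount 0) map to −∞ log-odds, so such a
base can never occur in a hit. Scores are log₂-odds sums ("bits") against
a uniform background by default — a genome-derived background is an
option, never a silent default, because uniform backgrounds keep the null
score exactly zero-mean and the oracles analytic. Both strands are always
scanned; coincident equal-score hits on a palindrome collapse to the +
strand. Hit positions are center-to-center: `offset` is the hit midpoint
minus the peak summit, and best-hit search requires |offset| ≤ window
(default 50 bp), with ties broken by smaller |offset| then leftmost.
The default hit threshold is 0.8 × the consensus score — an explicit,
config-visible choice, since percent-with-motif readouts are only
comparable at a stated stringency. Motif-presence reports both the
fraction of peaks with a hit and the mean best-hit score, the two
readouts of "motif stringency".

## Spacing

Distances at shared peaks are signed and center-to-center (second factor
minus first), matching a density-over-signed-distance view of co-binding
geometry. The KS D statistic is computed from first principles by
evaluating both ECDFs at the pooled unique values (tie-safe; verified
against an exhaustive double-loop oracle), with the asymptotic Kolmogorov
p at D·(√nₑ + 0.12 + 0.11/√nₑ); a permutation p is available for small n.

Classification: a pair is `random` if the distances are consistent with a
uniform reference (KS p > α = 0.01, one-sample implemented as two-sample
against a dense 10n-point grid); otherwise `constrained` if the robust SD
(1.4826·MAD) is ≤ 3 bp, else `relaxed`. The 3 bp boundary and α are
package defaults exposed in config — the constrained/relaxed distinction
is inherently a graphical one and these defaults simply make it
reproducible. The uniform reference half-width defaults to 2·window (both
factors free within the scan window); when the first factor is
summit-anchored — as in the synthetic generator and the pipeline, where
motif A is planted at the summit — the non-coordinated reference is
uniform over ±window, and `null_halfwidth=window` must be used. Under
full independence of both offsets the true null is triangular, not
uniform; the uniform reference is a deliberate simplification and the
anchored geometry is the one the calibration guarantees cover.

## Target calling

A gene is a TF target iff (i) expressed (count ≥ 1) in ≥ 25% of
TF-positive cells (TF-positive = raw count ≥ 1), (ii) log₂ fold change
≥ 0.223 versus all TF-negative cells, and (iii) bound (≥ 1 peak assigned
within 3 kb). Fold change uses per-10k normalized means with pseudocount
1, the standard single-cell marker-gene convention (0.223 ≈ log₂ 1.17, a
typical marker threshold). All thresholds inclusive; the rule is monotone
(raising any threshold can only shrink the target set). The out-group
defaults to all TF-negative cells; a cluster contrast is configurable,
and both choices are recorded in output metadata.

## PL-MS enrichment

Missing values are imputed from Normal(μ − 1.8σ, (0.3σ)²) where μ, σ are
the observed total-matrix moments — the conventional downshifted-normal
("total matrix mode") defaults, pinned as config values because
missingness in LFQ data is low-abundance-biased and the imputation model
presumes exactly that. Bait normalization subtracts the bait's log₂ value
per sample; it is applied per contrast (by default only where promoter
strength confounds expression of the ligase fusion).

The moderated statistic is t = (mean_a − mean_b)/(SE_pooled + s0), the
SE-inflation form: s0 = 0 recovers the pooled Student t exactly (tested
to 1e-9), and s0 = 0.5 (default) damps the small-variance instability of
triplicate designs.

Significance uses a permutation FDR: the matrix-wide |t| is recomputed
under label reassignments — exhaustive over all distinct assignments when
there are ≤ 10,000 (a 3v3 design has 20, of which the identity and its
complement are excluded because they reproduce the observed |t| exactly
and would floor the estimate at 2/n_perm regardless of effect size) —
and a protein's estimated FDR at its own |t| threshold is

    FDR(t) = [ (1 + total null ≥ t) / (1 + n_perm) ] / #{observed ≥ t},

with add-one smoothing so a finite permutation set can never report an
estimated FDR of exactly zero (the permutation analogue of the never-zero
p-value rule). Estimates are monotonized from the top so the significant
set is always an |t|-threshold set. Note that this estimator is monotone
in the FDR level but *not* protein-wise monotone in s0: raising s0
shrinks observed and null |t| together and individual ratio estimates can
move either way. High-confidence candidates must pass every configured
contrast in the positive direction, be detected (pre-imputation) in ≥ 2
replicates of the biotin-treated bait line, and be MS/MS-identified.

## Synthetic generators

Every generator is a pure function of (parameters, seed) — repeat calls
are bit-identical — and emits a truth table sufficient to score the
corresponding classifier without reaching into generator internals.

- *Counts*: exact two-level probability vectors sampled multinomially.
  Not modeled: doublets, ambient RNA, gene–gene correlation, zero
  inflation beyond multinomial sampling.
- *Genomes/peaks*: i.i.d. uniform-ACGT background (keeps null log-odds
  zero-mean and analytic) with PWM-sampled sites; motif A centered on the
  summit, motif B at offset + Normal(0, jitter) (constrained: jitter ≤ 3
  bp; relaxed: 3–30 bp) or uniform within ±50 bp (random). Not modeled:
  GC bias, repeats, overlapping peaks, indirect binding.
- *Occupancy*: folded-normal noise |N(0, amp/10)| everywhere plus a
  147 bp plateau of height amp at nucleosomal summits. Not modeled:
  phasing, fuzziness, digestion bias.
- *LFQ*: per-protein abundances Normal(25, 2) on the log₂ scale shared
  across samples, replicate noise sd 0.5 (a typical LFQ replicate spread;
  the abundance spread and replicate noise are separate parameters),
  +effect in the bait group for enriched proteins, and
  missing-not-at-random dropout (cells below the matrix 25% quantile drop
  with the configured probability).

Because backgrounds are idealized, passing recovery tests demonstrates
correctness of the decision rules under their stated models — not
robustness to the artifacts of real libraries (mappability, antibody
efficiency, batch structure), which these generators intentionally omit.

## Pipeline

A flat, versioned YAML config drives six stages (entropy; annotate →
nuc_classify → motif_spacing; targets; plms). Unknown keys are errors —
no silent typo tolerance. A single global seed derives per-stage seeds by
XOR with a CRC of the stage name, so stages are independently
reproducible and full runs are byte-identical for a fixed config + seed.
Every output carries a `.meta.json` sidecar naming its stage, parameters,
and derived seed. A failed stage is recorded and its dependents are
skipped; the run report is machine-readable JSON.

Problem sizes in the demo and acceptance script (hundreds of cells,
peaks, and proteins; 10–50 replicate calibration runs) are chosen so the
statistical assertions are well-powered at the stated tolerances while a
full run stays interactive on a laptop CPU.

## Known limitations

- No BAM/bigWig input: peaks, tracks and counts enter as text formats;
  upstream read processing (alignment, peak calling, nucleosome calling)
  is out of scope by design.
- The overlap null ignores blacklist/gap structure (conservative).
- Asymptotic KS p-values are approximate below n ≈ 25 per sample; use the
  permutation option there.
- The spacing classifier assumes one best hit per factor per peak;
  multi-site grammars, strand orientation rules and three-factor joint
  spacing are not modeled.
- Exhaustive permutation nulls for 3v3 designs rest on 9 distinct
  |t| configurations; FDR estimates at levels much below ~0.05 are not
  resolvable at that design size.
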