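# Methods

## Scope and data model

`mztdecay` operates on gene × sample matrices of FPKM values from
stage-resolved RNA-seq of mouse oocytes and preimplantation embryos
(stages GV, MII, zygote, two-cell, four-cell; conditions wild type,
α-amanitin, maternal *Yap1* knockout, si*Tut4/7*, control), with ERCC
spike-in rows identified by a configurable identifier prefix (default
`ERCC-`) and a sample sheet carrying stage, condition, batch, replicate and
per-sample ERCC read percentage. Read alignment and FPKM quantification are
upstream of this package; so is any between-gene normalization (TPM,
quantile), which the decay criteria do not require.

## Normalization

FPKM is relative to library size, but the maternal transcriptome shrinks
several-fold across the MZT, so relative units understate decay. ERCC
spike-ins are added at constant mass per sample; the fraction of reads they
absorb therefore tracks the inverse of the biological RNA content, and

    factor_s = ercc_pct(reference) / ercc_pct(s)

rescales each sample to the absolute scale of the reference sample — by
convention the wild-type zygote, applied per batch (`batch_anchor`) when
samples were prepared in batches. The ERCC percentage is taken from the
sample sheet when present (it is read-derived in a real experiment); when
absent it is computed as 100 × spike-in mass / total matrix mass, a
documented fallback that is only valid when no per-sample distortion has
intervened between the true abundances and the matrix, because a scalar
distortion of all rows leaves that ratio unchanged.

After scaling, genes that never reach FPKM = 1 are removed, surviving
values below 1 are floored to 1, and the cluster analysis works on
log2(x + 1). Spike-in rows are controls, not maternal transcripts: they are
exempt from removal and flooring, and dropped before classification. The
canonical order is ERCC scaling → filter/floor → log transform; every
result object carries an ordered tuple of transform tags so tests can
detect any other composition. Flooring guarantees that all ratio criteria
have denominators ≥ 1, so no division-by-zero handling is needed anywhere
downstream.

## Cluster classification

Maternal transcripts are those with mean floored FPKM > 2 at GV (strict).
On stage means of E = log2(FPKM + 1) — replicates averaged arithmetically on
the working scale — the four decay clusters are defined by strict
inequalities in which one unit is a two-fold change:

| cluster | interpretation | system |
|---|---|---|
| I | M-decay (degraded GV → zygote) | E_GV > E_zyg + 1, E_zyg < E_2C + 1 |
| II | Z-decay (degraded zygote → two-cell) | E_zyg − 1 < E_GV < E_zyg + 1, E_zyg > E_2C + 1 |
| III | continuous decay | E_GV > E_zyg + 1, E_zyg > E_2C + 1 |
| IV | stable | E_zyg − 1 < E_GV < E_zyg + 1, E_2C − 1 < E_zyg < E_2C + 1 |

The systems are mutually exclusive (I/III differ in the zygote→two-cell
direction, II/IV likewise, and the GV→zygote conditions separate the
pairs); profiles on a boundary (e.g. E_zyg exactly = E_2C + 1) satisfy no
system and are reported as `unclassified` rather than force-assigned — the
tri-state `pandas` nullable boolean (`True`/`False`/`NA`) is used for every
dependence flag for the same reason, so "criterion not evaluable" is never
silently conflated with "criterion false".

Ratio-based set criteria operate on floored FPKM (pre-log), matching the
scale on which they are stated:

* Z-decay set: FPKM(GV) > 2, zygote/GV ≥ 1/2, two-cell/zygote < 1/2;
* ZGA-dependent: Z-decay genes whose two-cell/zygote ratio under
  α-amanitin is ≥ 1/2 (the treated zygote column is used as the denominator
  when present — treatment starts at the zygote stage — otherwise the
  wild-type zygote);
* YAP1-dependent: FPKM(GV) > 2, wild-type four-cell/GV < 1/2, and
  knockout/wild-type > 1 at the four-cell stage;
* TUT4/7-dependent: knockdown/wild-type > 2 at two-cell, intersected with
  wild-type two-cell/zygote < 1/3;
* late decay (cluster IV sub-analysis): two-cell → four-cell ratio < 1/2,
  by analogy with the two-fold convention used elsewhere.

All inequalities are implemented exactly as stated, strict where stated.

## Set statistics

Overlap percentages are **truncated**, not rounded, to two decimals
(`floor(10000·k/n)/100`, in integer arithmetic): this convention is what
reproduces reported values such as 1224/1724 → 70.99% and 568/909 → 62.48%,
which rounding cannot produce. Overlap significance is the hypergeometric
upper tail P(X ≥ k) computed by log-space summation of exact log-pmf terms
and reported as log10 p, so enrichments far below double-precision
underflow (log10 p ≈ −550 or −1700) remain representable; the test label is
recorded in the output for transparency, and the universe (default: the
maternal gene set of the run) is an explicit parameter. Replicate agreement
is the mean pairwise Spearman correlation within sample groups. Two-group
comparisons use the classical equal-variance two-tailed t-test with the
0.05/0.01/0.001 asterisk convention; two degenerate groups with equal means
return p = 1 by convention.

## 3′-UTR analysis

CPE (UUUUAU, UUUUAAU) and PAS (AAUAAA, AUUAAA) occurrences are counted as
distinct match start positions per element class on the sense strand, with
overlapping matches allowed and a position matching both variants of a
class counted once. DNA input is transcribed T→U; when several isoform UTRs
exist for one gene the longest is kept; a BED interval, when given, must
agree with the sequence length (0-based half-open convention). Control sets
for separating motif-count effects from length effects are built by greedy
1:1 nearest-length matching without replacement, targets processed in
decreasing length order, ties broken by lexicographic gene identifier —
chosen over binned resampling for determinism — with the absolute matched
median-length difference reported as a matching-quality metric.

## qPCR quantification

Relative levels follow the ΔΔCt model with amplification efficiency fixed
at 2 (perfect doubling): replicate Cts are averaged per assay and
level = 2^−(Ct_target − Ct_reference); fold-changes divide by the mean
control-group level, so the control mean fold is exactly 1.
3′-oligouridylation is the ratio of the oligo(dA)-primed level (normalized
to the exogenous Gfp control) to the random-primed level (normalized to
endogenous Gapdh); the mode-specific reference pairing is fixed. Polysome
matrices are divided by their mCherry spike-in row (equal mass added per
sample), which cancels per-sample capture efficiency and is idempotent.

## Synthetic data generator

The generator defines the conditions under which the pipeline is validated.
Five archetypes are planted — M-decay, ZGA-dependent Z-decay,
ZGA-independent Z-decay, continuous, stable — 200 genes each by default,
with per-gene baseline drawn uniformly from 6–10 log2(FPKM+1) units. Every
decaying transition drops by `1 + fold_margin_log2` units (default margin
1.0, i.e. one full log2 beyond the cluster decision boundary); flat
transitions sit one unit from the boundary. Perturbations stabilize the
ZGA-dependent Z-decay archetype by holding its post-zygotic stages at the
zygote level; the ZGA-independent archetype models the
perturbation-insensitive half of cluster II.

Observed values are 2^(log2 true FPKM + N(0, σ)) × d_s with multiplicative
log-normal replicate noise (σ = 0.2 log2 units by default, matching the
variance structure of FPKM data) and a per-sample library-distortion scalar
d_s drawn uniformly from [0.5, 2.0]. Spike-ins share one true abundance
(log-uniform, ~3–1000 FPKM) across all samples and receive the same noise
and distortion. The emitted ERCC percentage is `base_pct × d_s`: constant
spike-in mass in a distorted library occupies a share proportional to the
distortion, which is precisely the signal the normalization factor inverts.
The reference sample's distortion is pinned to 1 so that the zero-noise
pipeline recovers true values exactly rather than up to a common scale.
Batches, when requested, partition replicates so each batch contains its
own zygote anchor.

Synthetic UTRs have exactly planted CPE/PAS counts: motifs are embedded at
random offsets in background sequence that is rejection-sampled to be
motif-free, and the assembled sequence is re-scanned (junctions can create
accidental occurrences) and rebuilt until the counts are exact — making
motif tests exact rather than probabilistic. Default length ranges give
Z-decay UTRs (600–1200 nt, 2–5 CPEs, 2–4 PASs) longer, element-richer UTRs
than M-decay (120–350 nt, ≤1 of each). Ct tables are generated as
Ct = offset − log2(true relative level) + N(0, 0.1) in triplicate, with
Gapdh/Gfp reference rows at the offset; uridylation indices are 0.2 at
baseline rising three-fold at the two-cell stage for Z-decay transcripts
(after the GV–MII transition for M-decay), suppressed under *Tut4/7*
knockdown. Polysome profiles plant binding fractions 0.8/0.2 (GV/MII) for
M-decay and the reverse for Z-decay, times a per-sample capture efficiency
exposed by the spike-in row.

What the generator does **not** emulate: read-level sampling noise and gene
length effects (values are drawn at the FPKM level), transcriptome-wide
effect-size distributions (decay magnitudes are fixed archetypes, not
estimates of the mouse transcriptome), partial or heterogeneous
perturbation penetrance, correlated gene modules, and sequence evolution.
Passing tests therefore demonstrate correctness of the decision rules and
estimators under the stated noise model, not performance on real embryo
data, where effect sizes near the decision boundaries will blur cluster
membership.

## Numerical choices and edge cases

* Strict inequalities exactly as stated; boundary profiles unclassified.
* Percentages truncated via integer arithmetic (`10000·k // n / 100`).
* Hypergeometric tails via `logsumexp` of `hypergeom.logpmf`; tails whose
  support includes the whole distribution return log10 p = 0 exactly.
* An empty overlap numerator set makes the percentage not applicable
  (`None`), never 0.
* ΔΔCt recovery under Gaussian Ct noise is asserted distributionally
  (median and 95th percentile of per-assay relative error): a supremum over
  arbitrarily many Gaussian draws is unbounded, so a fixed per-assay bound
  is not a meaningful contract.
* The YAP1 criterion `knockout/wild-type > 1` sits exactly on its boundary
  for genes the knockout does not affect; at zero noise only floating-point
  rounding decides such genes, and tests treat them as boundary cases.
* Problem sizes in tests and the acceptance script (10⁵-profile classifier
  searches, 10⁴ motif strings, 1000-gene recovery runs, universe ≤ 12
  enumerations) were chosen to make each property decisive while keeping
  the whole suite in the seconds range.

## Known limitations

* The analysis is threshold-based by design; no dispersion estimation or
  FDR control is performed, because the decay criteria are deterministic
  fold rules.
* ERCC anchoring assumes the spike-in share responds only to library
  distortion; degradation biases that affect spike-ins and transcripts
  differently are not modeled.
* The hypergeometric model assumes sets drawn uniformly from a shared,
  correctly specified universe; the universe choice materially affects deep
  tails and is therefore an explicit parameter.
* qPCR quantification assumes perfect doubling per cycle; no
  amplification-efficiency calibration is implemented.
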