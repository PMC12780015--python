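# Methods

This note records the models, conventions and numerical choices behind
`scfocal`, in the order data flows through the package.

## Expression preprocessing

Counts matrices are genes x cells. Quality control keeps cells whose
detected-feature count (genes with count > 0) lies strictly inside
`(min_features, max_features)` — defaults 200 and 4,500 — and whose
mitochondrial-count percentage is strictly below `max_mito_pct` (default
12.5%, genes identified by the configurable symbol prefix `MT-`). All three
comparisons are strict; a cell at exactly 200 features or exactly 12.5%
mitochondrial content is removed. Filtering is idempotent and never touches
the gene set.

Log-normalization divides each cell by its total count, multiplies by
`scale_factor` (default 10,000, the common single-cell convention) and
applies log1p. Scaling z-scores each gene across cells with the **sample**
standard deviation (ddof = 1) and clips to ±10; zero-variance genes map to
all-zero rows. Cell-cycle module-score regression is deliberately not part
of scaling — the connectivity machinery downstream is independent of it, and
the scaled layer is plain z-scores.

Duplicate gene symbols encountered at load time collapse to the row with the
largest total count, ties broken by first occurrence.

## Directional signatures

A `DirectionalSignature` maps unique genes to signed nonzero scores.

- **Consensus** across measurement contexts: a gene is kept when the majority
  sign agrees in at least `min_sign_frac` (default 0.75) of the contexts
  where it is measured *and* the median absolute score is at least
  `min_median_abs` (default 1.0); the retained score is the median signed
  score. A score of exactly 0 carries no direction and is treated as
  unmeasured. The rule is a parameterized reconstruction of the
  consensus-signature idea (genes consistently up- or down-regulated across
  cell contexts); both thresholds are exposed.
- **Response** signatures from a bulk DE table keep genes with
  `|logFC| > mean(logFC) + sd_mult * sd(logFC)` (default `sd_mult` 2) and
  BH-adjusted p < 0.05. The symmetric single-cutoff reading of the
  "two standard deviations from the mean" rule is the default; a two-sided
  `mean ± k·sd` variant is selectable because the two readings coincide only
  when the logFC distribution is centered at zero. Genes with logFC exactly
  0 are dropped even when the threshold is negative, preserving the
  nonzero-score invariant.
- **Disease** signatures compare each tumor state (≥ 3 cells) to the pooled
  non-neoplastic reference: per gene, logFC is the log2 ratio of
  pseudo-counted de-logged means, `log2((mean(expm1 x_state)+1) /
  (mean(expm1 x_normal)+1))`, and p-values come from a two-sided Wilcoxon
  rank-sum test (tie-corrected normal approximation), BH-adjusted within
  state. The rank-sum test stands in for hurdle-model DE: the downstream
  machinery consumes only (gene, logFC, adjusted p) triples, so the simpler
  nonparametric test keeps the package self-contained without changing the
  contract. A per-subject variant compares one subject's tumor cells to the
  full normal reference.

## Connectivity

Connectivity is the Spearman correlation between a signature's scores and a
cell's scaled expression over the signature genes present in the matrix,
with average ranks for ties. Signatures sharing fewer than `min_overlap`
genes (default 10) with the matrix produce missing rows; a cell that is
constant over the signature genes produces a missing value. Being a rank
statistic, connectivity is invariant to any strictly increasing transform of
a cell's expression and to gene order.

Derived structure:

- **Drug similarity** — Pearson correlation between signatures over their
  per-cell connectivity vectors, missing values excluded pairwise; constant
  rows yield missing correlations.
- **Mechanism networks** — undirected edges between signature pairs whose
  similarity strictly exceeds a threshold (default 0.7).
- **Cell clustering** — pairwise Spearman correlation among cells on their
  connectivity vectors, Euclidean distance on the rows of that correlation
  matrix, Ward agglomeration, and per-k within-cluster sum of squares in the
  same coordinate space. WSS for k = 1 is always computed so the elbow
  statistic (largest relative WSS drop) is anchored; the elbow is reported,
  never auto-applied — k remains a user choice.
- **State means** — per-state mean connectivity, z-scaled per signature
  across states (sample sd; zero-sd columns report 0).

## State scoring

The per-cell gene-set score is a direction-less normalized mean rank: rank
all genes by scaled expression within the cell (average ties) and report
`(mean_rank(set) − (n+1)/2) / n`, bounded by ±(n−|S|)/(2n). This
single-sample form suffices because the meta-modules are up-only sets; the
bidirectional up/down variant is out of scope. Paired sub-modules
(NPC1/NPC2, MES1/MES2) collapse by averaging before assignment; argmax ties
break to the first state in alphabetical order. Hierarchy coordinates place
progenitor-like states on top: `y = max(OPC, NPC) − max(AC, MES)`; for y > 0,
`x = OPC − NPC` (positive toward OPC), otherwise `x = AC − MES` (positive
toward AC). The sign convention is fixed here since it only affects plotting.

Module scores bin genes into `n_bins` (default 24) equal-size bins by average
lognorm expression and subtract, per cell, the mean of `n_ctrl` (default 100)
seeded bin-matched control genes per set gene. Control pools exclude the set
itself (falling back to the whole bin if a bin holds only set genes), which
makes the score exactly the set-vs-background offset on constructed
fixtures.

## Perturbation splits and their characterization

`split_cells` labels a cell resistant iff ρ > τ and sensitive otherwise
(cells at exactly τ are sensitive; the strict `ρ > 0` reading of the
resistance definition leaves ρ = 0 to the sensitive side). τ is either fixed
(default 0) or the mean of the non-missing connectivities; cells without a
connectivity value stay unlabeled and are excluded downstream.

Proportion shifts are per subject: state composition within the resistant
and the sensitive population separately, differenced (each per-subject delta
vector sums to 0). Subjects lacking either population are dropped. Per
state, a two-sided paired signed-rank test across subjects (exact null for
small subject counts, via scipy's automatic switch) is BH-adjusted across
states. Note the exact two-sided signed-rank p cannot fall below 0.05 with
fewer than six subjects. Differential expression between the populations
reuses the disease-signature machinery (resistant over sensitive), and
group-wise connectivity comparisons use the continuity-corrected two-sided
rank-sum test.

## Moderated differential connectivity

Connectivities are variance-stabilized before linear modelling: Fisher's Z
(`atanh`, inputs clipped to ±(1 − 1e−7) so boundary correlations stay
finite) or `log2(ρ + 1 + 1e−6)` (the pseudo-count transform, guarded at
ρ = −1). Per signature, ordinary least squares on intercept + resistant
indicator + optional covariate dummies (e.g. subject id); the design is
checked for full rank and offenders named. Residual variances s² with df
residual degrees of freedom are shrunk toward a prior:

    s2_post = (d0·s0² + df·s²) / (d0 + df)

with (d0, s0²) estimated by moment-matching the log residual variances to a
scaled-F distribution (digamma/trigamma moments, trigamma inverse by Newton
iteration — the canonical published estimator, cross-checked against the
reference implementation in the test suite). The moderated t uses d0 + df
degrees of freedom; p-values are BH-adjusted across signatures. `prior_df`
overrides d0: 0 recovers ordinary OLS t-statistics, very large values shrink
every posterior variance to s0². Precision weights are not used:
connectivities are not counts and the count mean-variance trend does not
apply, so the transform + unweighted OLS is the documented route.

Per-subject tables aggregate by the arithmetic mean of log2FC over subjects
where the signature was estimable. Predicted-versus-observed log2FC
agreement is summarized per annotation class by Spearman correlation with
the two-sided t approximation (df = n − 2), classes with fewer than 3 shared
signatures skipped.

## Reversal and combination scoring

The discordance ratio filters the disease table to adjusted p < 0.05 (the
disease-side significance filter is a package choice, exposed as
`disease_alpha`), then counts shared genes whose signs oppose
(discordant) or match (concordant) between signature score and disease
logFC; genes with a zero on either side count for neither. The ratio is
discordant/concordant, +inf when concordant = 0 < discordant, and missing
when both are 0.

The combination index is `log2FC × ρ̄`, defined only when both the
aggregated differential connectivity and the mean resistant-cell
connectivity are strictly negative; present values are min-max scaled to
[0, 1] (a single present value scales to 1.0). The end-to-end reference
pipeline scores reference + candidates, splits on the reference at the mean
connectivity, fits the moderated model per subject (skipping subjects
lacking both populations), aggregates log2FC across subjects, computes ρ̄
over the pooled resistant cells, and applies the index. The index is applied
to the cross-subject mean log2FC, matching the aggregate-then-weight order
of operations. Combination analyses operate on neoplastic cells only;
non-neoplastic reference cells exhibit marker-gene dropout that makes them
spuriously concordant with any reversal signature and would wash out ρ̄.

## Synthetic atlas generator

The generator emulates the features of a multi-subject droplet scRNA-seq
tumor atlas that this package's statistics actually consume:

- **Marker-like state modules.** Each state owns `genes_per_module` genes
  with low baseline relative expression (natural-log offset −2.0 from an
  average gene, sd 0.25) that are elevated in that state's cells. Elevation
  is *graded* across the module — from 1.5x down to 0.5x of the state mean —
  emulating strong-to-weak markers; the per-unit elevation scale is 2.0
  natural-log units per unit of `module_effect`, so the default
  `module_effect = 1.5` produces roughly a 1.5-sd shift on the scaled layer
  for the average module gene. `module_effect = 0` gives a null atlas.
- **Counts.** Gamma-Poisson (negative binomial) with dispersion 0.5
  (droplet-scale overdispersion), log-normal library sizes (sigma 0.3)
  around `mean_library_size = 1200` — about two counts per gene over the
  ~600-gene universe, matching the per-gene count density and ~50% sparsity
  of real droplet libraries — per-subject gene offsets (sd 0.15), and
  per-cell-per-gene biological log-noise with sd `0.5 × noise_sd`.
- **Signatures.** A state's targeting signature up-weights its module with
  rank-graded scores in [1, 2] aligned to the module's elevation grading
  (rounded to one decimal, so score ties occur), diluted with a fraction
  (default 0.1) of random-sign background genes; the reversal signature is
  its negation. Null signatures draw background genes with random signed
  scores. Bulk DE tables plant `n_sig` genes at ±effect with tiny p-values
  among near-zero null genes, BH-adjusted jointly.

All generators are pure functions of (spec, seed) and byte-identical across
runs. What the generator does **not** emulate: doublets, ambient RNA,
batch/chemistry effects, continuous state gradients or plasticity,
cell-cycle structure, and realistic tumor-microenvironment composition.
Tests passing on these fixtures demonstrate that the statistics recover
planted discrete-state structure under negative-binomial noise — not that
they resolve the subtler failure modes of real data.

## Problem sizes used in validation runs

The bundled recovery runs use a 4-state, 4-subject atlas with 200 cells per
state per subject (~3,600 cells x 605 genes) for split recovery, a 6-subject
variant for the proportion-shift test (the exact signed-rank test needs six
paired observations to reach p < 0.05), twenty 2-state replicates
(~330 cells each) for the combination benchmark, and twenty small null
atlases for false-discovery calibration. These sizes give stable recovery
statistics while keeping a full validation run in the seconds range.

## Known limitations

- Connectivity treats cells independently; no spatial or lineage structure.
- The rank-sum DE and unweighted moderated model are deliberate
  simplifications of hurdle-model DE and precision-weighted modelling; they
  preserve the contracts the downstream scoring consumes but are not
  drop-in replacements for those methods' inference on real data.
- The mean-threshold and zero-threshold splits are both exposed because
  either convention is defensible; results near τ are sensitive to the
  choice.
- Min-max scaling of the combination index is cohort-relative: scaled
  scores are not comparable across candidate sets.
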