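# Methods

`patagium` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the bespoke computational procedures of a
cross-species (bat vs mouse) single-cell dissection of limb development:
cell-level quality control, proximo–distal (PD) identity scoring, the
reciprocal derivation of a proximal/distal fibroblast gene programme,
cross-species concordance statistics, mutant-evaluation statistics, and
TAD-level aggregation of regulatory binding signal with a
density-inflection enrichment threshold. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic experiments do and do not establish.

## Quality control

QC operates per library ("sample"). With per-cell total UMI counts
$t_c$, ribosomal UMI fraction $r_c$ and genes detected $g_c$:

* **UMI bounds** — remove cells with $t_c > 4\,\overline{t}$ or
  $t_c < 0.2\,\mathrm{med}(t)$.
* **Ribosomal fraction** — remove cells with $r_c$ outside
  $\mathrm{med}(r) \pm 3\,\mathrm{MAD}(r)$. The MAD is unscaled by
  default (no 1.4826 normal-consistency factor); `mad_scale` is a
  parameter. The band is symmetric by default; an upper-only variant is
  selectable (`ribo_two_sided=False`), since a one-sided filter is a
  plausible alternative reading of this rule.
* **Low complexity** — remove cells with $g_c/t_c < 0.15$ **and**
  $t_c < \tfrac23\,\mathrm{med}(t)$. The conjunction is the default
  interpretation (the ratio clause alone would also strike large,
  genuinely complex cells); the disjunctive reading is selectable
  (`complexity_conjunction=False`). Both constants are parameters.

A haemoglobin-dominated-cluster filter (mean haemoglobin UMI fraction
above a threshold) is exposed explicitly and never applied
automatically. `apply_qc` is idempotent for fixed thresholds, and the
test suite checks its removal set against an independent brute-force
per-cell evaluation of the same formulas (exact set equality).

## Normalisation and variable genes

Log-normalisation is $x_{cg} = \ln(1 + 10^4\, n_{cg}/t_c)$ with the
scale factor 10,000 as the canonical default. Highly variable genes are
those whose variance of normalised expression exceeds
$\mathrm{med}(v) + \mathrm{MAD}(v)$ over genes (strict inequality, so a
flat variance profile yields an empty list).

## Module scores and the PD axis

The module score of a gene set $S$ in cell $c$ is

$\mathrm{score}_c(S) = \frac{1}{|S|}\sum_{g\in S} x_{cg} -
\frac{1}{|C|}\sum_{g\in C} x_{cg}$,

where the control pool $C$ is built by binning all genes into
`n_bins = 24` equal-count bins of mean normalised expression and
sampling, for each set gene, `n_ctrl = 100` control genes with
replacement from its bin (seeded). Set genes are excluded from the
control pools; this makes the constant-expression cases exact (score 0
when all genes share a value; score $c-d$ when set genes sit at $c$ and
the rest at $d$) and removes self-contamination for small sets.

The PD score is the distal-set score (*HOXD13*, *MSX1*) minus the
proximal-set score (*SHOX2*). Per cluster, the mean PD is ranked and the
top and bottom $\lfloor K/3\rfloor$ of $K$ clusters become very-distal /
very-proximal ("one third per extreme"; the fraction is a parameter).
Ties break lexicographically by cluster name, making the classification
deterministic and invariant to adding a constant to all scores.

**Typical proximal/distal genes.** A gene is typical-distal when, in
*both* species, it is detected (raw count > 0) in ≥ 20 % of the cells of
at least $\lceil 0.2K_d \rceil$ of the very-distal clusters, and its
log2FC against the pooled very-proximal cells exceeds 0.15 (symmetric
for proximal). The cluster quorum uses a ceiling so that the rule
remains meaningful with few clusters. Genes highly expressed in the
chondrogenic lineage are excluded; since no quantitative threshold is
canonical, this is operationalised as: mean expression in the
top-decile chondrogenic-module-score cells exceeding the global mean by
a configurable log2 margin (default 1.0).

Co-expression of two genes is the fraction of cells with raw UMIs of
both genes > 0, reported per cluster alongside the single-gene
detection fractions (the Fréchet bounds
$\max(0, f_X+f_Y-1)\le f_{XY}\le\min(f_X,f_Y)$ are property-tested).

## Differential expression

`wilcoxon_de` is a two-sided Wilcoxon rank-sum test on normalised
expression. Fold changes use the pseudocounted convention
$\log_2\frac{\overline{\mathrm{expm1}(x)}_{in}+1}
{\overline{\mathrm{expm1}(x)}_{out}+1}$. A gene is tested only when
$\max(\mathrm{pct}_{in},\mathrm{pct}_{out}) \ge$ `min_pct` and
$|\log_2\mathrm{FC}| \ge$ `lfc_threshold` (marker defaults 0.25 / 0.5).
P values are exact when the smaller group has ≤ 8 cells and the total is
≤ 30 (a tie-aware dynamic programme over the permutation distribution of
the observed mid-ranks; verified against full enumeration for all group
sizes with $n_1+n_2\le 12$), and a tie-corrected normal approximation
otherwise; the switch points are parameters. Benjamini–Hochberg
adjustment runs across tested genes only. Under a pure null the
realised fraction of $p<0.05$ sits at the nominal level (0.045 on 5,000
simulated NB genes in the test suite).

## The fibroblast programme

`derive_programme` runs two reciprocal comparisons in the species-B
forelimb: distal fibroblasts vs all cells except proximal fibroblasts,
and proximal fibroblasts vs all cells except distal fibroblasts.
Round 1 restricts to the highly variable genes with the marker gates;
round 2 re-tests both comparisons on the union of round-1 DE genes
(BH < 0.05) with no gates, so every union gene receives a log2FC in both
comparisons. The union (rather than intersection) of the round-1 sets
is used: the programme explicitly contains distal-only and
proximal-only genes, which an intersection would exclude by
construction. The **shared** programme is the genes with log2FC > 0.1
in both round-2 comparisons (and enriched, BH < 0.05 with log2FC > 0.1,
in at least one); distal-only / proximal-only are the enriched
complements. The **cross-species-shared** subset contains shared genes
whose one-to-one orthologue is enriched by the same rule in the other
species' proximal fibroblasts.

Cross-species concordance pairs per-gene log2FCs through the orthology
(computed with near-zero gates, 10⁻⁴, so every gene of interest is
reported) and flags $|\Delta\log_2\mathrm{FC}| \le 0.25$; the summary is
the within-band fraction. For this comparison both species use a
background of matching cluster composition (both fibroblast
compartments excluded), so planted-identical effects are compared like
for like.

Mutant evaluation substitutes the same Wilcoxon engine for the original
covariate-adjusted hurdle regression (covariate-adjusted hurdle models
are out of scope): genes are pre-filtered to ≥ 15 % detection in either
genotype with chrX / mitochondrial / ribosomal genes excluded,
over-representation of DE genes in the programme uses the upper-tail
hypergeometric test with the background universe defined as all genes
detected in at least nine cells, and per-cell similarity to the
reference distal-fibroblast state is the Pearson correlation of each
cell to the mean normalised programme-gene profile of the reference
cluster (zero-variance cells reported as missing).

## TAD-level regulatory enrichment

Intervals are 0-based half-open. Per TAD, the signal AUC is
$\sum_i v_i\,\ell_i$ over overlapping bedGraph steps (mean = AUC / TAD
length; additive under splitting a TAD), and peak coverage is the merged
peak base count divided by TAD length. Enrichment thresholds come from
`density_dividing_point`: a Gaussian KDE of the per-TAD values on a
512-point grid padded by 3 bandwidths, with bandwidth
$1.06\,\hat\sigma\,n^{-1/9}$ — the $n^{-1/9}$ rate appropriate for
estimating a second derivative rather than the density itself (plain
Silverman leaves sampling wiggles that masquerade as shoulders). The
second derivative (central differences) defines concave runs of the
density; runs whose curvature depth is below 5 % of the maximum
curvature, or that lie where the density is below 10⁻⁴ of its peak, are
discarded as noise. With at least two substantive concave runs
("bumps"), the dividing point is the convexity onset (f″ crossing
negative → positive) in the gap adjoining the bump that carries the
global mode — beyond it when an upper subpopulation exists, before it
when the upper component itself carries the mode. Unimodal inputs have
a single bump: the threshold is `None` and a fallback flag is set. An
explicit antimode method (density minimum between the two highest
modes) is provided as an alternative. Enrichment flags use strict
inequality (recorded in the output metadata); the mean signal per TAD
drives the flags by default, with total AUC selectable, since both
aggregations are defensible.

Genes map to TADs by TSS containment (genes outside all TADs stay
unassigned). Candidate genes are programme genes whose TAD is enriched
for **both** signal and coverage; the top 20 by TAD signal are selected
and additionally ordered by acetylation-style coverage for display, and
both orderings are emitted.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

* **Design** — two species × two limbs (defaults: mouse FL/HL, bat
  FL/HL), six clusters per block with roles (proximal fibroblast, distal
  fibroblast, interdigital retinoic-acid, chondrogenic, other); the
  distal-fibroblast cluster exists only in the species-B forelimb, the
  design's analogue of the wing membrane population. Default 140 cells
  per cluster (≈ 3,000 cells), 5,000 genes, 200 TADs of 100 kb.
* **Counts** — gamma–Poisson (negative binomial, dispersion 0.15) with
  log-normal library sizes (median 5,000 UMIs, σ = 0.3) and per-cluster
  relative-expression vectors: a base gene-weight profile (log-normal,
  σ = 1.5) scaled by $2^{e}$ for the planted genes of the cluster's
  role. Marker genes carry log2 effects of 1–2.5; the planted programme
  is 150 shared, 25 distal-only and 60 proximal-only genes at log2
  effect 1.0. Planted genes sit in the moderately-expressed range with
  a log-normal (σ = 0.4) dynamic range, as real programmes do. The
  per-cell ribosomal weight share is pinned to a sampled target fraction
  (uniform on [0.04, 0.06]) so the MAD-based QC rule sees a controlled
  distribution.
* **Planted structure** — QC-failing cells per rule (extreme library
  sizes, extreme ribosomal fractions, low-complexity cells restricted to
  the 40 most-expressed genes); a co-expressed gene pair with an exact
  joint-detection probability per cluster (Bernoulli gating: the gate
  forces joint detection, its complement zeroes the second gene);
  species-B-specific genes that are left out of the orthology to
  exercise orthology-restriction code paths; a TAD signal mixture
  (bulk mean 1.0, enriched mean 3.0, component SD 0.25 — an 8-SD
  separation — enriched weight 0.2) with per-bin gamma noise and peak
  coverage targets of 2–10 % (bulk) vs 30–50 % (enriched).
* **Seeding** — one top-level seed; per-block substreams are spawned
  from a `SeedSequence`, so adding a block does not perturb earlier
  blocks and identical spec + seed reproduces byte-identical outputs.

**What the generator does not emulate:** ambient RNA, doublets, batch
chemistry, read-level error, realistic gene-gene correlation beyond the
planted programme, per-gene dispersion heterogeneity, and integration
artefacts. Passing tests therefore establish the correctness and
calibration of the procedures under the stated generative model, not
performance on real libraries.

## Problem sizes in the test and acceptance runs

The suite's simulation-based checks use the stated study conditions:
QC-oracle equality on ≈ 1,000 cells; PD recovery with six 200-cell
clusters at marker effect 1.0 over 20 seeds; programme recovery at
5,000 genes with ≥ 300 cells per fibroblast compartment over 10 seeds
(plus 20 zero-effect null seeds); dividing-point recovery at n = 10,000
over 50 + 50 seeds; concordance at ≈ 1,000 cells per species. The
acceptance script runs the full pipeline once at the default
≈ 3,000-cell scale and reports recovery of every planted structure.

## Known limitations

* The Wilcoxon substitution for the hurdle-regression mutant analysis
  ignores covariates (library, ribosomal fraction); systematic shifts
  along those covariates would confound the genotype test.
* The dividing point assumes the enriched subpopulation is separable in
  one dimension; heavily overlapping mixtures return the fallback
  rather than a forced threshold.
* Gene→TAD assignment by TSS containment ignores genes whose regulatory
  domain differs from their TSS's TAD.
* Orthology is strictly one-to-one; many-to-many homology is out of
  scope.
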