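# Methods

## Statistical model

All screens are Spearman rank correlations computed on pairwise-complete
observations: for each (predictor, target) pair, samples missing either
value are dropped, both vectors are ranked with average ranks for ties, and
ρ is the product-moment correlation of the ranks. Two-sided p-values use
the large-sample t approximation, t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
freedom. At panel sizes of interest (tens to hundreds of lines per
stratum) this approximation is standard; exact permutation p-values are
intractable at epigenome scale and are not offered. Pairs with fewer than
`min_n` complete observations (default 10, the stratum-eligibility floor)
or with a constant ranked vector are skipped but still counted toward
their multiple-testing family.

Multiplicity is handled by Benjamini–Hochberg step-up adjustment over
*explicitly declared* families: the family size m is a stated product —
agents × GMDs for the direct screen, GMDs × regions for the stage-1 region
screen, agents × unique stage-1 targets for stage 2, each optionally × the
number of cancer categories for stratified runs — never simply the number
of p-values that happened to be computed. When m exceeds the observed
count, the missing combinations enter as implicit p = 1 tests; this only
affects the m in the numerator, making the accounting conservative and
reproducible. Probe-level stage-1 selection instead uses fixed raw-p cuts:
10⁻⁶ (a published epigenome-wide threshold for single-gene association
scans on 450K arrays) divided by the number of GMDs screened, and further
divided by the number of cancer categories for within-category runs. With
the study-scale defaults of 72 GMDs and 23 categories these derive, at
four significant digits, to 1.389 × 10⁻⁸ and 6.039 × 10⁻¹⁰; the stratified
cut is computed from the rounded pancancer value, matching how such
thresholds are conventionally printed.

Stratified FDR has two defensible readings: one pooled family spanning all
categories with an ×n_categories multiplicity factor, or a separate family
per category. The pooled ×k mode is the default (`fdr_mode=
"pooled_times_k"`); the per-stratum mode is available behind the switch.
Neither is presented as uniquely correct.

A methylation hit is *cis* when the target probe's annotated gene list (or
the region's gene) contains the screened GMD's symbol, otherwise *trans*;
intergenic probes are trans by convention. Cis hits are reported but
interpreted separately, since a GMD's own promoter methylation (or copy
number) can drive both its expression and its methylation signal.

## Probe QC

Three rules, thresholds inclusive exactly as stated: (1) individual betas
with detection p ≥ 10⁻³ are set missing; (2) probes with median detection
p across samples ≥ 10⁻⁶ are removed; (3) probes on the hg19 SNP-overlap
mask list are removed. The median in rule 2 is computed on the original
detection matrix, which makes rules 1 and 2 commute; whether the original
analyses ordered them differently is unknowable from their description,
and this choice is documented rather than attributed. Missing betas are
represented by an explicit NaN (0 is a valid beta) and propagate as
pairwise-unavailable; no imputation is performed.

## Region averaging

Regions are identified purely by the manifest annotation strings — a
(gene symbol, category) pair with category in {TSS1500, TSS200, 5′UTR,
1st exon, gene body, 3′UTR} — with no coordinate arithmetic, so strand and
coordinate-base conventions are delegated to the annotation file. A probe
annotated to k distinct pairs contributes to k regions; duplicate pairs
within a probe collapse to one. Region values are unweighted arithmetic
means of the non-missing constituent betas per sample ("averaged" is read
as the arithmetic mean; the IMA lineage of region summarisation also
offers medians, which are not used here). There is no minimum probe count:
a single-probe region is valid. The epigenome average is the per-sample
mean beta over all QC-passing probes.

## Mutation-conditional regression

For candidates strongly associated (|ρ| > 0.5) with response to an agent
whose sensitivity has known genetic drivers, ordinary least squares fits
log10(IC50) on three indicator covariates — BRAF V600E, any
non-synonymous KRAS variant, any non-synonymous NRAS variant — plus the
expression/methylation predictor, with two-sided t-tests per coefficient.
"Non-synonymous" covers every protein-changing class (missense, nonsense,
frameshift, splice, in-frame indels). The three flags enter as separate
indicators rather than a combined RAS flag. Flags constant within the
complete cases are dropped with a warning and the model refit, so a
stratum with no carriers degrades gracefully to the marginal regression.
Predictor p-values are BH-adjusted over the candidate family; flag
p-values are reported raw. No robust/sandwich errors are used.

## Synthetic panels

The generator emulates the statistical structure the screens assume, not
any real cohort. Every observable is a strictly monotone map of a latent
standard normal, so planting a latent Pearson correlation r = 2·sin(πρ/6)
yields a population Spearman correlation of ρ between the observables —
the copula construction makes target correlations analytically
controllable and invariant to the marginal transforms.

- **Expression** is exp(μ_g + z), RPKM-like and nonnegative, μ_g ~
  N(1.5, 1).
- **Methylation** probes within a region share a region latent with
  weight `region_correlation` (default 0.5). Betas are
  logistic(a_p + 1.5·latent) with the intercept a_p drawn around a region
  category base (upstream categories ≈ −2 to −2.8, gene body +1.6,
  3′UTR +1.2, intergenic +0.3; spread 1.4), giving the bimodal
  near-0/near-1 distributions characteristic of array betas, skewed
  unmethylated upstream of the TSS and methylated in gene bodies.
- **Drug response** is log10(IC50)-scaled (μ_a + 1.2·latent, μ_a ~
  N(−1, 1)) with a 5% missing rate per agent; agent ids carry a
  dataset-of-origin suffix.
- **Detection p-values** for passing probes are 10^−U(8,16), far below
  both QC cuts; a `detection_fail_rate` fraction of entries (default 1%)
  is redrawn ≥ 10⁻³, and `n_failing_probes` whole probes can be planted
  above the median cut. SNP-masked probes are sampled away from planted
  effects so QC never silently destroys a planted signal.
- **Planted effects** rewire latents: trans effects target a probe (or a
  whole region, whose probes then share one latent so the region average
  carries the exact planted ρ); cis effects correlate a GMD's own
  upstream-region latent negatively with its expression; stratum-specific
  effects mix latents only within that category's samples; mutation
  effects add a log10(IC50) shift in Bernoulli(0.15)-flagged carrier
  lines (the spec'd correlation field has no natural additive scale, so
  the shift is a separate parameter, default magnitude 1.0 with the sign
  of `rho_target`); epigenome-average effects correlate a global latent
  with a GMD and mix it (variance share 0.2) into all unplanted probes —
  the probe-averaged mean then tracks the global latent closely. The
  global latent is only created when an effect references it, so
  no-effect panels have independent probes (up to region sharing) and are
  usable as calibrated nulls.
- A **ground-truth ledger** records each planted effect with its realized
  within-stratum Spearman correlation measured on the generated
  observables, plus per-kind pair counts for null accounting.

One integer seed feeds hierarchically spawned per-table RNG streams
(structure, expression, methylation, drugs, mutations, detection), so a
table is reproducible even when unrelated tables change size, and the same
seed yields byte-identical panel files.

Default shapes (200 lines, ~10 genes of each kind, ~10³ probes) are scaled
roughly an order of magnitude below a 645-line / 485k-probe study panel;
the chain-recovery and calibration analyses use 600 lines with ~400 probes
and 20 seeds, sizes at which a planted ρ = 0.7 has essentially full power
against the 1.389 × 10⁻⁸ cut while a full generate–screen cycle stays in
the seconds range.

What passing on synthetic panels does **not** show: robustness to batch
effects, copy-number-driven beta artifacts, cell-line identity errors,
non-monotone expression–methylation relationships, 5-mC/5-hmC confounding
(indistinguishable on bisulfite arrays), or the correlated mutation
backgrounds of real lineages. The generator also does not simulate raw
IDAT intensities or EPIC-array manifests.

## Numerical choices and edge cases

- ρ is clipped to [−1, 1] before the t transform; |ρ| = 1 maps to p = 0.
- BH adjustment uses a stable mergesort and a reverse cumulative minimum;
  ties in p preserve input order. NaN p-values pass through unadjusted.
- Region averages ignore NaN per sample and return NaN only when all
  constituent betas are missing; a region with no probes in the matrix is
  omitted rather than emitted empty.
- Result tables are sorted by (p_FDR, |ρ| descending, ids) with a stable
  sort, so repeated runs are byte-identical and diffs are meaningful.
- Malformed annotation rows (unpaired gene/category lists, unknown
  category labels) are rejected with the probe named, never guessed.
- Duplicate (agent, sample) response measurements are averaged at load
  time with a logged count.

## Known limitations

- The t-approximation p-values are anti-conservative for n near the floor
  of 10; stratified hits at minimal n deserve extra scrutiny.
- Correlation screens are marginal: no covariate adjustment (beyond the
  dedicated mutation-conditional model), no partial correlations, no
  lineage random effects.
- The pooled ×k stratified FDR mode treats strata symmetrically although
  category sizes differ widely.
- Pearson-mode screens and EPIC-manifest region averaging are out of
  scope.
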