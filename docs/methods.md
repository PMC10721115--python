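# Methods

`cocoex` implements the statistical pipeline of a cross-species coculture
transcriptomics experiment: human neurons differentiated on a monolayer of
mouse glia, sequenced in bulk, with reads assigned to species by alignment
to a combined human–mouse reference. Because human and mouse reads separate
by genome, the same RNA library yields two expression profiles — one for the
neurons, one for the glia — and the analysis asks, in both directions, how
the state of one cell population associates with gene expression in the
other.

## Alignment QC

Aligning human reads once against the human genome alone and once against
the combined reference gives two paired count matrices. For each gene the
two log-CPM vectors are stacked (every sample appears twice, labelled by
alignment) and a balanced two-way fixed-effect ANOVA with samples as blocks
partitions the variance; the per-gene statistic is SS(alignment)/SS(total).
With exactly two observations per (sample, alignment) cell this fixed-effect
decomposition coincides with the mixed-model variance partition in the
balanced case, which is why the simpler form is used. Genes whose fraction
reaches the threshold (default 0.10, boundary included) are flagged as
alignment-sensitive. Two global tests accompany the per-gene fractions: a
paired t-test on per-sample total counts (the combined reference loses a few
percent of reads to cross-species ambiguity) and a Mann–Whitney test on gene
length, flagged vs rest (cross-mapping genes tend to be short). The
Mann–Whitney p is computed by exact enumeration when both groups are ≤ 50
and tie-free, otherwise by the tie-corrected normal approximation. The
degenerate paired case (all differences equal and nonzero, zero variance) is
reported as p = 0 with an explicit `degenerate` flag rather than raising.

## Preprocessing

* **Replicate summation.** Libraries sharing a replicate group are summed
  column-wise into one integer library; totals are conserved exactly.
* **Expression filter.** A gene is kept iff its maximum count over libraries
  exceeds 10 *and* its total exceeds 15. The rule is deliberately literal
  (a gene at [10, 10, 10] is removed despite a total of 30) and idempotent.
* **TMM normalization.** The reference sample is the one whose
  75th-percentile count fraction is closest to the mean. Per sample,
  log2 ratios (M) against the reference are computed over genes positive in
  both, doubly trimmed — 30% per tail on M, 5% per tail on average abundance
  A — and averaged with inverse delta-method-variance weights; the factor is
  2 to this mean, and factors are rescaled to geometric mean 1 (enforced to
  1e-12). The implementation reproduces edgeR's `calcNormFactors(method="TMM")`
  to ~1e-8 on fixture matrices.
* **log-CPM.** `log2((count + prior) / (libsize·factor + 1) × 1e6)` with
  prior 0.5 by default. The exact prior is not critical; 0.5 matches the
  common limma-voom convention. log-TPKM divides by gene length in kb first
  and rescales each sample's rates to one million before the log.
* **Precision weights.** Following the voom recipe: per-gene OLS residual
  square-root standard deviations are smoothed against average log2 count by
  lowess (span 0.5, exposed), the trend is evaluated at each observation's
  fitted log-count (constant extrapolation beyond the range), and the weight
  is the predicted value to the power −4, floored at 1e-6 before inversion.
* **Batch adjustment** is a deliberate location–scale method: per gene, each
  batch is centered to the pooled mean and scaled to the pooled SD. No
  information is pooled across genes, so singleton batches are an error and
  small batches are adjusted noisily; it is not an empirical-Bayes batch
  model and is documented as such.
* **Dispersion summaries** use the method of moments on library-size-scaled
  counts, `phi = max(0, (s² − m)/m²)`, reported as mean and median over
  genes with positive mean.

## Marker eigengenes

The astrocyte state of each coculture is summarized by an *eigengene* over
six canonical astrocyte markers (Aldh1l1, Slc1a3, Slc1a2, Gfap, Notch1,
S100b) measured in the mouse fraction: the marker × sample log-CPM submatrix
is row-centered and (by default) row-scaled — the scaling keeps any single
highly variable marker from dominating — and decomposed by SVD. Scores are
the first right singular vector, loadings the first left one, and variance
explained is d₁²/Σd². Orientation is fixed by requiring positive
correlation between the scores and the column mean of the standardized
marker block, so a high eigengene always means high marker expression. When
leading singular values tie exactly the component is not identifiable; the
code returns numpy's deterministic SVD output under the same sign rule.

Glia-free cultures have no mouse reads, so their astrocyte signal is by
definition absent; they are assigned a baseline score of zero and enter the
downstream regression as ordinary observations. An alternative
*extrapolated* baseline projects a glia-free sample's marker values (which
sit at the detection floor) onto the fitted loadings:
`u'((x − centers)/scales)/d₁`. The same SVD machinery applied to the set of
astrocyte-induced neuronal genes yields the *neuron eigengene*, a
per-culture neuronal maturation proxy.

## Per-gene association

Every gene's normalized expression is regressed on a shared design —
`~ AstroE + ngn2` for human genes (Ngn2 transgene level z-scored), `~ NeuroE`
for mouse genes — by batched (weighted) least squares. Residual variances
are then moderated with the standard empirical-Bayes closed forms: the prior
(d₀, s₀²) comes from moment matching on log residual variances via
digamma/trigamma inversion, the posterior variance is the
degrees-of-freedom-weighted average, and the moderated t gains d₀ degrees of
freedom. The estimates agree with limma's `eBayes` to ~1e-5 on fixtures.
One deliberate difference: when the observed variances show no excess spread
over the chi-squared sampling baseline, the prior df is capped at 1e6 and
the prior variance is set to the mean observed variance, so that identical
gene variances pass through moderation unchanged.

Multiplicity is controlled by BH step-up q-values (FDR 5%) and a Bonferroni
flag at α/m, with the transcriptome-wide threshold reported at two
significant figures. Donor structure, where present, is adjusted as fixed
indicator covariates; the interface accepts any covariate set so a
random-effect backend could be swapped in without contract changes.
Per-covariate variance fractions use a type-I decomposition on sequentially
orthogonalized, centered covariates, so fractions plus residual sum to 100%.

Aggregate statistics: `aggregate_shift` z-standardizes each gene across all
samples pooled over conditions (pooled standardization chosen; the
alternative per-condition scaling would distort the difference of means),
takes the per-gene mean difference between conditions, and summarizes over
the gene set with a one-sample t-test. `marker_class_shift` regresses the
per-sample mean of z-scored class-gene expression on a group indicator
(sample-level aggregation chosen as the unit of analysis);
`marker_class_contrast` is a Welch t-test between the pooled gene×sample
values of two marker classes on the log-TPKM scale.

## Meta-cells

Single-cell UMI counts from a pooled "village" culture are summed into one
meta-cell per (donor, condition); entries are exact integer sums, and the
number of cells, mean UMI per cell and donor sex travel along as DE
covariates (near-constant covariates are dropped automatically to keep the
design full-rank). Differential expression between conditions then runs on
the meta-cell matrix exactly like bulk.

## Enrichment statistics

Over-representation uses the upper-tail hypergeometric test within an
explicit universe — the genes actually analyzed, never the full annotation —
with set sizes restricted to [10, 1000] within the universe and BH applied
across tested sets, within each namespace separately when namespaces are
given. Overlap tests are exact binomials; the two-sided p aggregates all
outcomes no more likely than the observed one (the minimum-likelihood
convention of standard exact tests), with a one-sided alternative
selectable. Fold enrichment is observed/expected: `k/(n·K/N)`. The
competitive gene-set test regresses gene-level Z statistics on a membership
indicator (one-sided p for positive enrichment); cell-type specificity
z-scores each gene across cell types and compares the focal type's z of the
set genes against the pooled other types by Welch t-test.

## Synthetic data

The generator produces the inputs the analysis assumes, with truth records:

* A latent astrocyte-abundance factor `a_s ~ N(2, 1)` across cocultures
  (the location is arbitrary — an eigengene is location/scale-free — but a
  positive mean makes the zero assigned to glia-free cultures a true
  extrapolation of "no astrocytes"). Monocultures have the factor exactly 0.
* Marker genes' log2-CPM is `8 + loading·(a_s − 2)` with loadings
  `~ N(2.0, 0.2)`; at the default depth this puts ~95% of each marker's
  variance on the shared factor, matching the near-rank-1 structure the
  eigengene assumes.
* A responsive subset of human genes (default 5% of the transcriptome)
  follows `base + β_g·a_s + γ_g·ngn2_s` with `β_g ~ N(1, 0.3)` log2 per
  factor SD and an independent standard-normal Ngn2 covariate per sample
  (no distribution is prescribed for the transgene; Gaussian on the log
  scale is the neutral choice). A mouse responsive subset follows the same
  factor, standing in for glial genes that track neuronal maturation.
* Sandwich (membrane-separated) cultures receive an independent latent
  soluble-exposure factor and a contact deficit (default 0.5 log2) on
  responsive genes; modelling contact as a *deficit in sandwich* rather
  than a bonus in coculture keeps the coculture-vs-monoculture regression
  exactly linear in the factor.
* Counts are negative binomial via a Gamma–Poisson mixture with dispersion
  0.1 (between the study's reported monoculture and coculture dispersion
  summaries); dispersion 0 degenerates to Poisson, and `count_noise="none"`
  switches to deterministic rounding of expected counts for exactness tests.
  Base expression is uniform on [1, 8] log2-CPM, library sizes ~5 million
  with 10% CV.
* The paired mixed-reference matrix applies binomial thinning at 3.9% to
  every library (thinning preserves integer counts, unlike scaling) and an
  additional per-sample uniform loss up to 50% to a designated cross-mapping
  gene subset.
* The village generator gives every donor a fixed number of cells in each
  condition, per-cell depths around a configurable mean, and a constant
  log2 condition effect on responsive genes.

What the generator does *not* emulate: compositional coupling between the
two species' library fractions, gene–gene correlation beyond the shared
factor, batch/timepoint structure, length biases, ambient RNA or doublets in
the village, and donor genetic effects. Passing tests therefore demonstrate
that the statistical machinery recovers the structure it assumes at
realistic noise levels — not robustness to the full messiness of real
coculture data.

## Problem sizes and numerical choices

The default simulated transcriptome is 2,000 human / 1,500 mouse genes with
28 cocultures + 4 monocultures; the full-scale end-to-end run uses 16,000
human and 11,000 mouse genes over 32 samples, the scale of a filtered bulk
experiment. Calibration suites use 40–50 replicate simulations. All
randomness flows through `numpy.random.default_rng` seeded from the config,
so identical configs give bit-identical outputs. Degenerate inputs are
handled explicitly: all-zero samples are errors for TMM/TPKM, zero-variance
marker rows are errors under row scaling, an all-identical paired difference
yields p = 1 (zero) or a flagged p = 0 (nonzero), and fractions with zero
total sum are reported as 0.

## Known limitations

Donor adjustment is fixed-effect, not the correlation-based blocking of a
random-effects fit; the batch stand-in shares no information across genes;
the eigengene is a single component and will blur multiple glial
sub-states; the competitive gene-set test assumes independent gene-level
statistics; and the ORA universe handling assumes the caller supplies the
analyzed-gene universe.
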