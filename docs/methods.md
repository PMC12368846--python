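# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limits of what the test suite can and
cannot show about real data.

## The data and its two structural problems

A cell-sorted methylation study profiles several purified nuclei
fractions per donor on a methylation array; each site yields a *beta
value* in [0, 1]. Two features distinguish these data from bulk-tissue
EWAS. First, the same donor contributes up to one sample per fraction,
so observations are correlated within donor. Second, the scientific
question is two-dimensional: is a site associated with the phenotype at
all, and if so in which cell type(s)? The package's regression
frameworks, benchmark harness and two-stage pipeline exist to answer how
those two features should be handled.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a
convenience fixture. Defaults mirror the reference cohort design: three
analysed fractions (NeuNPos n=182, Sox10Pos n=168, DoubleNeg n=164)
drawn from 218 donors; donor age uniform on 18–100 years, two sexes,
eight brain banks; case/control assigned at the donor level.

Per autosomal site *s* and cell type *c*:

* the baseline mean comes from a three-component mixture (35% hypo near
  0.10, 30% intermediate near 0.5, 35% hyper near 0.90 — beta-shaped
  components whose only consequential role is how often values clamp at
  the boundaries);
* a fraction of sites (default 30%) get cell-type-specific mean offsets
  (SD 0.15, clipped into [0.05, 0.95]). The NeuNPos offsets are scaled
  3.5× larger than the glial fractions', reproducing the dominant axis
  of sorted cortical data (NeuN+ vs NeuN−): leading PCs separate the
  fractions cleanly and joint quantile normalization transforms the
  neuronal fraction hardest, as observed on the real cohort;
* the site SD σ_{s,c} is drawn from a log-normal matched by mean/SD to
  the printed per-fraction moments (0.036/0.023, 0.038/0.024,
  0.057/0.033). Larger SDs are rank-paired (with noise) to
  intermediate-methylation sites, reflecting the empirical mean–variance
  relationship of beta values and keeping exact-0/1 clamping below 1% of
  values;
* a sample's value is `clamp[0,1]( m + σ(√w·u_i + √(1−w)·ε) )` with
  donor intercept u_i ~ N(0,1) shared across the donor's fractions and
  variance share w = 0.2 by default. The cross-fraction residual
  correlation of a donor therefore equals w; the within-donor
  correlation is a single knob because no published estimate of its
  value exists for these data.

Special site classes give the normalization metrics signal: imprinted
DMRs (mean 0.5, σ 0.02 in every fraction), SNP probes (donor genotype at
{0.03, 0.5, 0.97}, shared across the donor's fractions), and X-linked
sites (females near 0.5, males near 0.15). Covariates carry no signal by
default (models still adjust for them); a flag plants small age/sex
effects at 1% of sites for confounding experiments.

Spiked DMPs add a fixed delta (default 0.05) to case samples of the
affected cell types — all types for "common" DMPs, one uniformly chosen
type for "cell-specific" ones — then clamp to [0, 1]; attenuation at
boundary sites is deliberate realism. Sorting failures are label swaps
(values untouched) and convex mixtures with another fraction's mean
profile.

What the generator does **not** emulate: probe-type chemistry and
background signal, missing values, batch/technical noise, heavy-tailed
or polymorphic-probe SD outliers beyond the log-normal, and any
phenotype structure beyond a binary label. Passing tests therefore show
that the statistical machinery behaves as designed under a clean
Gaussian-on-beta-scale model matched to the study's first two SD
moments, not that real arrays meet those assumptions. The simulations
are parametric: it is unknown whether the original study resampled
observed arrays or simulated parametrically, so this generator is a
documented stand-in with matched structure.

## Regression frameworks

All frameworks share one fixed-effect structure: intercept, case, cell
type, case×cell type (pooled frameworks only), age (centered), sex, and
brain bank (dummy-coded). Cell type uses treatment coding with the
alphabetically first label (DoubleNeg) as reference — the reference
choice matters for interpreting interactions and is configurable and
recorded in every result.

* **ctLR** — OLS within one cell type, t test on the case term,
  vectorized by sharing the design pseudo-inverse across sites.
* **allLR** — pooled OLS with classical SEs. This is intentionally
  misspecified on sorted data in two ways: it ignores within-donor
  correlation, and its pooled residual variance understates the
  reference fraction's sampling noise whenever cell types are
  heteroskedastic. The second effect alone inflates the main-effect test
  (the pooled σ ≈ 0.045 vs the DoubleNeg sampling SD ≈ 0.057 implies
  |z| inflated ~1.27×), which is the mechanism behind the dozens of
  null false positives per study that the benchmarks reproduce.
* **MER** — per-site random-intercept model. The variance ratio
  λ = σ_u²/σ_e² is profiled: after an orthonormal rotation built from
  the donor-cluster structure (cluster means vs Helmert contrasts), the
  covariance is diagonal with at most four distinct weights, so the REML
  criterion for *every* site at a grid λ costs one p×p solve. A 61-point
  log grid on [10⁻⁴, 10²] (plus λ=0) is refined per site by parabolic
  interpolation in log λ; the final GLS is batched over sites.
  Inference is Wald with the asymptotic normal reference; Satterthwaite
  degrees of freedom are deliberately omitted (they would slightly
  deflate tail p-values, and the reference implementation comparison in
  the tests bounds the consequence at ~10% relative on p). REML is the
  default; the λ=0 constraint (`max_ratio=0`) recovers allLR exactly.
* **CRR** — allLR point estimates with a CR1 cluster-robust sandwich
  (scale G/(G−1)·(N−1)/(N−k)), t reference with G−1 df, G = donors.
  With singleton clusters this reduces exactly to HC1.

Calling policy: for pooled frameworks a site is significant if the main
effect *or any* interaction passes ("any-term", default), with
"main-only" and "joint-test" selectable; ctLR calls on its case term.
Zero-variance sites are flagged non-converged and excluded from calls
but never dropped from output.

## Benchmarks and threshold calibration

Null benchmarks re-randomize the phenotype on a fixed cohort per
simulation (matching how repeated null EWAS are constructed from one
dataset); spiked benchmarks additionally draw fresh DMP sites each
simulation. Per-simulation seeds derive deterministically from the
master seed via `SeedSequence.spawn`. The 5% family-wise-error threshold
per framework/term is the linearly interpolated 5th percentile of the
per-simulation minimum p-values — the standard permutation-FWER reading
of "mean 5% family-wise error rate"; a mean-of-per-simulation-quantiles
estimator is available behind a flag but not default.

ctLR true-positive denominators are the DMPs that *affect* the analysed
cell type: a within-NeuN regression cannot, even in principle, detect a
DMP confined to oligodendrocytes, so counting such DMPs against it would
conflate design coverage with statistical power. Pooled frameworks are
scored over all DMPs. Default scales — 50,000 sites for null studies
(scaled from the array's ~846k; false-positive bounds are conservative
under scaling), 1,000 spiked + 5,000 null sites for spiked studies —
keep a 100-simulation study within minutes on one CPU.

On this synthetic cohort the measured mean true-positive rates at
9×10⁻⁸ run a few points above the reference study's grid-averaged
figures for the within-cell-type analyses (the study itself prints both
0.76 and 0.91 for ctLR-NeuN at the same threshold under different
conditioning; our per-DMP rates fall between the two), while the pooled
CRR/MER rates and the false-positive ordering match closely. The
residual gap is consistent with real site-SD distributions being
heavier-tailed than a two-moment log-normal.

## Power module

Power is the two-sided noncentral-t power of the two-sample t-test
(df 2n−2, noncentrality δ√(n/2)/σ) at α = 9×10⁻⁸; where scipy's
noncentral t underflows (huge noncentrality) the normal limit is used.
Site-SD profiles are binned into 500 equal-count bins; the bin's mean SD
gives one Cohen's d and one power value for all its sites (binning error
< 1 percentage point on ≥10k-site profiles, verified against the
unbinned computation). Required sample size uses doubling plus bisection
to the exact minimal integer; a `paper_grid` option reproduces the
coarser 100-point grid search for comparability. Detectable difference
scans the grid 0.001…0.100 (step 0.001, proportion scale); the CLI
reports differences in percentage points. Testing is two-sided by
default with a one-sided option.

## QC

PCA is computed on the site-centered matrix over all samples (full SVD;
an option restricts to the most variable sites for speed), with the sign
convention that each component's largest-magnitude loading is positive.
The isolation efficiency score is the **max** over a donor's samples of
the Euclidean norm of per-PC z-distances to the labelled cell-type
centroid (max, not mean, so a single failed fraction flags the sort),
with per-cell-type per-PC SDs and a flagging threshold of 5. The
retention filter requires |z| ≤ 2 separately on each of the first two
PCs, computed in a single pass — iterating would shrink the SDs and
over-exclude. A consequence worth stating: with Gaussian within-type
scores the 2-SD rule excludes ~9% of clean samples in expectation; a
"clean data are all retained" reading would require pooling SDs across
cell types, which contradicts the per-cell-type z definition used by the
isolation score. Array-quality and identity checks (stages 1–2) need
raw array channels and are present only as not-evaluated placeholders.

## Normalization comparison

Between-sample quantile normalization (rank-wise replacement by the mean
order statistic, average ranks at ties) stands in for
probe-type-stratified methods, since probe chemistry is not modelled;
absolute metric values on synthetic data are therefore not comparable to
published real-data tables, only the joint-vs-per-cell-type contrast is.
DMRSE is the SE across samples of per-sample imprinted means; GCOSE the
mean squared deviation of SNP-probe values from the nearest of
{0, 0.5, 1}; seabird is 1 − AUC (Mann–Whitney, on the per-sample
X-linked mean, oriented into [0, 0.5]) — a per-sample-summary
simplification that is monotone-equivalent to per-site AUC averaging for
this comparison.

## Two-stage pipeline

Stage 1 fits ctLR per cell type and takes the union of sites passing the
discovery threshold (default 9×10⁻⁸; relaxation is refused beyond
10⁻⁶, where the null benchmarks show false positives stay below one per
study). Stage 2 refits only discovered sites with the mixed model and
classifies by the joint Wald test on all interaction terms at a
Bonferroni-adjusted 0.05 over the discovered set: heterogeneity detected
→ cell-specific, with affected cell types read from per-cell contrasts
at nominal 0.05; otherwise common — explicitly a non-rejection, not
proof of a shared effect. A per-term heterogeneity option exists behind
a flag. Stage 2 never adds sites absent from stage 1.

## Numerical and degenerate-input conventions

Determinism everywhere: every stochastic operation takes a seed, and
identical seeds give byte-identical outputs. Zero-variance sites are
detected exactly (max = min across samples). Rank-deficient designs
raise an error naming the collinear columns. Quantile normalization's
tie rule makes idempotence exact only on tie-free data (boundary-clamped
values are the one realistic source of ties). REML λ̂ at the grid
boundary λ=0 is kept at zero rather than refined. All matrices are
dense float64; a 100-simulation null study at 50,000 sites peaks around
1 GB.
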