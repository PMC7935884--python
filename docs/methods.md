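# Methods

This note documents the statistical models, numerical conventions, and
design choices behind `wormtrauma`. It is the package's own account of
its science; every number quoted here is recomputed by the test suite or
by `scripts/acceptance.py`.

## The screen statistic and its error model

Large-particle flow cytometry ("worm sorting") measures, for every
detected object, a time-of-flight (TOF, an axial-length proxy), an
extinction (optical density), and fluorescence channels. In a
neurodegeneration screen, worms expressing GFP exclusively in
dopaminergic neurons are injured, and the population-mean GFP retained
48 h later — relative to age-matched uninjured controls — quantifies
neuronal survival. For each RNAi knockdown the screen reports a
normalized protection index

    index = (EV − RNAi) / (EV − 1)

where `EV` and `RNAi` are each the ratio of injured to uninjured
population-mean GFP for the empty-vector control and the knockdown,
respectively. The anchors follow directly: a knockdown whose injured
worms retain full fluorescence (`RNAi = 1`) scores 1; one that loses as
much as the control (`RNAi = EV`) scores 0; values below 0 mean the
knockdown worsened the loss. The index is invariant to any common
rescaling of the fluorescence axis (detector gain), and is strictly
increasing in the RNAi retention ratio for `EV < 1`.

Uncertainties propagate in quadrature at every stage:

1. Each population mean carries its SEM (`sd/√n`, `n−1` denominator).
2. Each ratio `R = m_i/m_u` carries
   `δR = R·√((sem_i/m_i)² + (sem_u/m_u)²)` (quotient rule).
3. The per-replicate index error treats EV as the experiment-wide
   constant of that replicate: each ratio uncertainty enters as
   `δX/(1 − EV)` and the contributions add in quadrature.
4. Across biological replicates, the per-replicate errors combine as the
   error of a mean (`√(Σδ_r²)/n`, the "within" term), the SEM of the
   replicate indices forms the "between" term, and the two add in
   quadrature to `δ_total`. The 95% interval is `index ± 1.96·δ_total`.

Hit calling is the interval rule: protective when the interval lies
entirely above 0, sensitizing when entirely below. The exact
per-condition tests behind any particular published hit list are
figure-level metadata we do not reproduce; the interval rule is an
explicit, documented approximation.

### What the error model does and does not guarantee

Treating EV as a constant in step 3 makes the propagated error exact at
index ≈ 0 (where it coincides with full first-order propagation of both
ratios), mildly conservative for strongly protective genes, and mildly
anticonservative for sensitizing genes — the derivative of the index
with respect to the EV ratio scales with `(1 − RNAi)`. Separately, when
there is no genuine day-to-day variability, the between term re-estimates
the same sampling noise the within term already carries, so `δ_total`
overstates the error; when day-to-day effects dominate, `n = 3`
replicates with a z-interval (1.96 rather than a t₂ quantile) understate
it. Neither regime is pathological — they bracket 95% — and the contract
we state and test is end-to-end *coverage*: under the default simulation
conditions (3 replicates × 500 worms/arm), the 95% intervals cover the
planted index in 93–97% of gene-conditions (measured 95.5% over 800).
The Monte-Carlo checks validate the quadrature machinery itself
(single-replicate error and the combined within term, both within 10% of
10⁵-draw oracles at relative errors ≤ 5%, asserted near index 0 where
the constant-EV form is exact). A fixed-summaries Monte-Carlo cannot
validate `δ_total` directly, because its between term is estimated from
the observed replicate scatter; the coverage band is the operative
guarantee.

The degenerate-control guard rejects experiments with `|EV − 1| ≤ 0.02`
(configurable): if injury removed no fluorescence from the control arm,
the index is undefined.

## Synthetic data: what it emulates, and what it does not

All inputs can be generated with planted ground truth; recovery tests
are the package's acceptance surface.

**Flow events.** Optical channels are lognormal — cytometry intensities
are positive and right-skewed, and multiplicative injury effects act
naturally on the log scale. The published source data never states
per-worm intensity distributions; lognormality is this package's
modeling choice. Defaults: TOF median 400 a.u. (σ=0.25), extinction 300
(σ=0.25), GFP 200 (σ=0.5), live-worm red 5 and dead-worm (propidium-
iodide-positive) red 500 (σ=0.4), separated by the default death
threshold of 50. Contaminant classes are parameterized relative to adult
medians: larvae at 0.25×, bacterial debris at 0.02×, doublets as the
channel-wise sum of two adult draws, curled worms at 0.55× TOF with
1.4× extinction. Injury is a two-component mixture: a Bernoulli fraction
(default 0.7) of worms has GFP multiplied by a loss factor (default 0.4
for the control), the rest retain healthy signal — matching the per-worm
heterogeneity in which some injured animals keep intact neurons. The
generator does not model sorter optics, spectral overlap, carry-over, or
time-dependent drift; gate-purity results on synthetic data therefore
speak to the gating logic, not to any particular instrument.

**Screen experiments.** For a planted index `I` the injured-arm GFP
factor is the algebraic inversion `f_g = 1 − (1 − I)(1 − f_EV)`, which
makes the population-level index equal `I` in expectation regardless of
the affected fraction (it cancels). Day-to-day biological variability is
modeled as Gaussian jitter on each gene's per-replicate index
(`replicate_index_sd`, default 0.08). The default equals the
per-replicate sampling error of the index at the default scale (3
replicates × 500 worms/arm), so the within and between error sources are
comparable — the regime in which the quadrature error model above is
approximately calibrated; see the coverage analysis. Jitter is truncated
so the implied GFP factor stays in (0, 1]; the resulting bias on planted
means is < 0.002 index units at the default jitter. Random streams are
keyed hierarchically by (gene position, replicate, arm), so adding genes
to a screen never perturbs existing draws.

**Stress-transcriptome fold changes.** Each dataset's per-gene log2 fold
change is a weighted sum of latent stress "programs" plus Gaussian
noise: `x[d,g] = Σ_p L[d,p]·E[p,g] + ε`. The implied dataset-by-dataset
covariance is `L·Cov(E)·Lᵀ + σ²I` with `Cov(E)` the empirical (n−1)
covariance of the program effect vectors, so the true correlation matrix
is available in closed form; at σ = 0 the empirical Pearson matrix of
the generated data equals it exactly. NaN entries are injected uniformly
at random. The generator makes no attempt to emulate platform-specific
missingness, probe effects, or count overdispersion.

**Assay tables.** Quadrant counts are multinomial; paralysis and
nose-touch responses binomial; qPCR Ct values follow
`Ct = baseline − log2(level) + noise` with both housekeeping genes at
the baseline, and a configurable fraction of technical replicates is
flagged with two melt peaks (and a +10-cycle shift, so failing to
exclude them is detectable).

## Gating

Thresholds are config-driven; `GateConfig.from_reference` derives
defaults from the adult medians of an uninjured reference table, because
published gate settings are instrument-specific: rectangle lower bounds
at 0.5× the medians, a bacterial-debris box at 0.1×, a doublet bound at
1.7× the median extinction (a linear bound with configurable slope), and
a curl region at TOF < 0.6× with extinction > 1.2×. Flags are assigned
in the fixed order bacteria → larva → doublet → curl, first match only.
The debris box exists because larvae and bacteria both fail the lower
rectangle bounds on both channels and cannot be distinguished by a
single threshold. Intervals are closed-left/open-right: events exactly
on a lower bound are retained. Propidium-iodide-positive (dead) events
are counted but retained — death is a measurement, not a contaminant.
Gating is idempotent, and on fixtures whose class centers sit ≥ 4 SD
from every boundary (σ = 0.02 lognormal spread), per-class purity and
recall exceed 99%.

Percentile selection (for sorting the dimmest or brightest worms) uses
linear-interpolation percentile thresholds with a [lo, hi) band, closed
at the top for hi = 100, so bands that partition [0, 100] partition the
table.

## Transcriptome operations

Differential expression is a per-gene two-sided Welch t-test on log2
values, with fold change as the ratio of group means on the linear
scale. Significance requires `|FC| ≥ 2` (inclusive) and `p ≤ 0.05` —
raw p for array-style analysis, Benjamini–Hochberg q for
sequencing-style analysis. The beta-binomial count test used by
commercial RNAseq software is deliberately not reimplemented; the
package's thresholds-and-overlap logic is the point, and the Welch+BH
path is the documented stand-in. Genes with zero variance in both groups
get p = 1. Zero-variance, significance-monotonicity, and an exhaustive
BH check against the step-up definition (all nondecreasing p-vectors of
length ≤ 5 on a 0.1 grid, plus seeded fine-grid vectors and a
permutation-equivariance property) pin the implementation.

Cross-correlation restricts all datasets to a reference gene set,
z-normalizes each (n−1 sd), drops every gene that is NaN in *any*
dataset (complete-case, matching a concatenate-then-filter workflow;
pairwise-complete is available as an option), and computes the Pearson
matrix. Correlating log2 fold changes is the default; since Pearson
correlation is affine-invariant per dataset, the z-normalization step
changes nothing numerically but mirrors the published procedure. Fewer
than 3 complete-case genes is an error.

The age-trend comparison is a paired two-sided t-test on log2 fold
changes of the same stress-activated genes at two ages, reporting the
mean difference and the count of genes above the 2-fold threshold at
both ages. Identical inputs give p = 1 by convention rather than NaN.

The candidate funnel intersects significance with annotation flags
(transcript abundance > 1, neuronal expression, mammalian homolog, RNAi
clone availability); genes missing from the annotation table fail
closed.

## Assay metrics

Chemotaxis: `(#attractant − #control) / #total`, bounded in [−1, 1] and
antisymmetric under swapping the quadrant counts. Worms that stay in the
neutral center circle count in the denominator but in neither tally —
the formula's denominator is the total scored; this convention is ours,
as the source procedure is silent on it. Paralysis and death fractions
carry Wilson 95% intervals. Nose-touch scoring uses the worm, not the
trial, as the unit: each worm contributes one percent-positive value
over its five touches, and mean ± SEM is taken over worms. qPCR uses the
ΔCt method with two housekeeping transcripts (defaults `tba-1`,
`Y45F10D.4`): technical replicates with > 1 melt peak are excluded, the
remaining Cts averaged, and ΔCt is the target mean Ct minus the
arithmetic mean of the two housekeeping Cts — algebraically identical to
normalizing the target's `2^−Ct` level by the geometric mean of the two
housekeeping levels (verified to 1e−12). Amplification efficiency is
assumed 100% (`2^−ΔCt`); no efficiency correction is applied.

## Numerical conventions and degenerate inputs

- sd uses the n−1 denominator everywhere; single-observation populations
  report zero spread by convention.
- Thresholds stated as "≥" are inclusive, including fold change exactly
  at 2.0.
- Empty tables, all-gated-out tables (reported with the dominant gate),
  constant vectors under z-normalization, degenerate EV controls, and
  fully melt-excluded qPCR cells raise typed errors
  (`ConfigurationError` vs `DataError`), which the CLI maps to exit
  codes 2 and 3.
- All generators are deterministic given (config, seed);
  `full-run` outputs are byte-identical across invocations.

## Problem sizes used by the test and acceptance suites

Simulation scales are chosen to make the statistical contracts sharp at
desk scale: 200 screens × 4 scored genes for interval coverage, 100
screens for effect-recovery rates, 10⁵–10⁶ draws for Monte-Carlo and
brute-force oracles, 2000 genes for correlation recovery at noise 0.2,
and 20 000-event tables for gate purity. These sizes give binomial
standard errors comfortably inside the asserted bands.

## Known limitations

- The hit-calling intervals are normal-theory with n as small as 3
  replicates; the coverage analysis above quantifies the consequences
  under the default conditions and does not transfer automatically to
  real screens with different noise structure.
- Passing recovery tests on synthetic data shows the pipeline computes
  its statistics correctly under the stated generative model, not that
  the model captures any particular instrument or biology.
- The DE path assumes approximately log-normal intensities; it is not a
  count model.
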