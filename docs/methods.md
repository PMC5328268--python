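# Methods

## The analysis population

One record per measured individual: forest id, species id, leaf size (cm²)
and/or SLA (cm²·g⁻¹). A present trait value must be positive; a record may
miss one trait and still serve the other trait's analyses. Species identity is
the verbatim name string (no taxonomic normalization), and a species name
occurring in two forests forms two independent analysis groups, because every
statistic here is computed within a forest. Both the pooled species count and
the (forest, species) group count are reported, since they answer different
questions. A group enters a trait's analyses only with ≥ 5 non-missing values
of that trait (`filter_min_individuals`, k = 5 by default; k is exposed
because the floor is a sampling-design choice, not a law).

## Rarefied ITV

The coefficient of variation, CV = 100·s/x̄ with the n−1 sample sd, is
sample-size biased, and sampling effort per species ranges from 5 to ~70
individuals. Each group is therefore rarefied: `n_reps` (default 1000) random
subsets of `n_draw` (default 5) individuals are drawn without replacement, and
mean, sd and CV are computed per subset and averaged across subsets. Averaging
the per-subset statistic (rather than taking CV of the averaged mean and sd)
is the standard rarefaction estimator and is applied uniformly to all three
statistics; the alternative composition is available as
`aggregation="of_averages"` because the two readings differ slightly whenever
subset means vary. With exactly `n_draw` values every subset is the full
sample and the estimator reduces to the plain statistics; as `n_reps` → ∞ it
converges to the exhaustive all-subsets average, which `exhaustive_stats`
computes directly for small pools and the tests use as the exact reference.

Randomness: every (forest, species, trait) group draws from a substream keyed
by the master seed and the group's identity (SHA-256 of the key feeding a
`SeedSequence`), and values are put in canonical sorted order before drawing,
so results are independent of input row order and identical seeds give
bit-identical output.

Two diagnostics probe whether the 5-draw CV is trustworthy: `rank_stability`
(rarefied CV at draws of 5 vs 10 or 20 among species with enough individuals;
the r² of the rank–rank fit should be near 1) and `sample_size_bias_check`
(median/quartiles of CV across sample-size bins; medians should not trend with
n). Community accumulation curves are not implemented: what they should
accumulate is underdetermined, and the two diagnostics above are the operative
checks.

## Trait overlap

Overlap of two species is ∫ min(f₁, f₂) dx ∈ [0, 1].

**Normal assumption.** With fᵢ = N(μᵢ, σᵢ²) the integrand switches branch at
the density crossings, the roots of a quadratic obtained from
log f₁ = log f₂. For σ₁ = σ₂ there is one crossing at the midpoint and
O = 2Φ(−|μ₁−μ₂|/2σ); otherwise there are exactly two crossings x₁ < x₂, the
narrower density exceeds the wider one between them, and
O = Φₐ(x₁) + 1 − Φₐ(x₂) + Φᵦ(x₂) − Φᵦ(x₁) with a the narrower and b the wider
density. The implementation is vectorized over pair arrays; the tests verify
it against adaptive quadrature (with breakpoints at the crossings — without
them the quadrature itself is only ~1e−6 accurate) to 1e−8 across a
1000-point parameter sweep. μ and σ are the rarefied mean and sd, so the
normal estimator inherits the rarefaction's sampling-effort correction.
Degenerate σ = 0 (all individuals identical) is defined as overlap 1 for
coincident point distributions and 0 otherwise.

**Kernel density.** Gaussian KDE per species on the raw individuals with the
nrd0 rule-of-thumb bandwidth 0.9·min(s, IQR/1.34)·n^(−1/5) (falling back to
s, then |x̄|, then 1 when spread estimates vanish), both densities evaluated
on one 512-point grid spanning the union of the two sample ranges ± 3
bandwidths, each renormalized to unit mass on the grid, and the pointwise
minimum integrated by the trapezoid rule, clipped to [0, 1]. Whether the
original analyses fed the kernel raw individuals or rarefied subsamples is
not documented; raw individuals are the default here because discarding data
the estimator can use is hard to justify, and the rarefied-moment route
already exists as the normal method.

Overlap is computed on the raw trait scale for every unordered pair of
sampled species within a forest (S·(S−1)/2 pairs); forests with fewer than
two qualifying species are excluded from summaries and logged. Per forest the
pair values are reduced to the median and the shares strictly below 0.25 and
strictly above 0.75 — strict, following the verbal definitions "less than" /
"higher than".

## Inference

**ITV model.** Gaussian linear mixed model of log CV on species richness,
mean annual temperature (°C) and annual precipitation (mm), with a random
intercept per forest type (statsmodels `MixedLM`, REML). The log scale is the
default because CV is positive and right-skewed and because reported
coefficient magnitudes for this kind of analysis are consistent with a
log-scale response; `family_config="gaussian"` fits the identity scale
instead. A Gamma/log-link variant is not offered: no installed mixed-model
implementation supports it. Fixed-effect p-values use t statistics with
n − p residual degrees of freedom. Marginal and conditional R² follow the
fixed/random/residual variance decomposition: R²ₘ = var(Xβ̂)/(var(Xβ̂) + σ²ᵤ +
σ²ₑ) and R²꜀ adds σ²ᵤ to the numerator. When the random-intercept variance is
estimated on the zero boundary (or the fit fails), the model falls back to
OLS with a warning and R²꜀ = R²ₘ — the ordering R²ₘ ≤ R²꜀ holds by
construction in both branches.

**Summary regressions.** OLS of √(summary) on species richness, one point
per forest, for each of the three summaries; the square-root transform is
applied to all three (they live in [0, 1] and are right-skewed at the low
end). A constant response is defined to have slope 0, r² = 0, p = 1 rather
than the indeterminate value OLS produces.

**Estimator comparison.** Wilcoxon signed-rank on paired per-forest medians
(normal vs kernel): zero differences dropped, absolute differences midranked,
W⁺ compared to its null mean n′(n′+1)/4 with variance n′(n′+1)(2n′+1)/24 −
Σ(t³−t)/48 for tie groups of size t; the signed Z is kept internally (it
flips sign when the inputs swap) and reported as |Z| with the two-sided
normal p. The tests check the approximation against full sign-assignment
enumeration for n ≤ 12 and against an independent library implementation.

## The synthetic gradient generator

The generator emulates the field campaign's data shape: 21 forests on the
study's richness ladder (1–284 species/ha), a per-species individual count
that mirrors real effort (15–40 individuals in species-poor forests, 5–15 in
hyperdiverse ones; `effort_rule="constant"` for fixed counts), and heavy
subsampling of species in rich forests (default min(richness, 50) species
measured; the study's own per-forest sampled counts are available as
`STUDY_SAMPLED`).

Species trait means are placed evenly **on the log scale** within the trait
range (default 5–250 cm² for leaf size), jittered uniformly by ±25% of the
inter-mean spacing — leaf traits are positive and span orders of magnitude,
so "evenly spaced" is applied on the scale the trait lives on. The community's
full richness packs the axis; the campaign samples a random subset of those
positions. Within-species values are lognormal with the requested mean and CV
(default leaf size 45%, SLA 40%; leaf-size CVs reported for real communities
range far higher, but raw-scale moment estimation from 5-individual draws of
very heavy-tailed distributions is noise-dominated, so the default sits at
the realistic lower-middle of the range), or normal (truncated positive) when
the closed-form overlap ground truth `expected_overlap_profile` is wanted.

The three scenarios differ only in two rules. `A_high_itv_poor`: spacing
fixed (range grows with richness), CV constant — overlap flat and low.
`B_shrinking_itv`: range fixed, CV declines linearly with richness — ITV
falls, overlap roughly constant. `C_constant_itv_fixed_range`: range fixed,
CV constant — spacing shrinks, overlap rises while ITV stays flat, the
pattern the empirical analysis found. Climate covariates are
richness-correlated by default (MAT ≈ 8 + 0.07·SR ± 2.5 °C,
AP ≈ 600 + 9·SR ± 250 mm), mimicking the boreal→tropical confounding;
`climate_coupled=False` makes them independent. Forest types are quantile
bands of richness (≥ 2 types whenever richness varies), giving the random
intercept something to group on.

What the generator does **not** emulate: real communities have clumped,
phylogenetically structured trait distributions, abundance-dependent
sampling, measurement error, and covarying traits; species here are
independent lognormal bumps with a single latent axis per trait. Passing
pipeline tests on these data shows the estimators and inference behave
correctly under the stated generative assumptions, not that real forests
follow scenario C.

A structural property of scenario C worth knowing: with means evenly packed
in a fixed range, the *median* pairwise separation converges to ~0.29× the
range once S exceeds ~10 (the pair-separation distribution approaches the
triangle law), so the median-overlap response saturates beyond richness
~30 and the richness trend in the median is carried mainly by the
species-poor forests, whose medians rest on 1–6 pairs. The tail shares
(< 0.25, > 0.75) do not saturate this way and show the scenario's signal far
more reliably. This is why, across repeated synthetic gradients, the
sqrt-median regression on richness is significantly positive in roughly four
of five replicates while the tail-share regressions are significant in
nearly all.

## Numerical and interface choices

- All Monte-Carlo stages (rarefaction, generator, subsampling) use
  numpy `Generator` substreams keyed by seed + stable identity; identical
  configs are byte-identical, and row order never matters.
- Problem sizes in the test suite: enumeration oracles use pools ≤ 8;
  estimator-consistency checks use 100–200 samples over 40–100 seeds; mixed
  model recovery/coverage use 200 replicates of 300 observations; the
  full-pipeline scenario check uses 100 replicates of the 21-forest gradient
  at 1000 rarefaction replicates.
- Workbook output mirrors the four-sheet layout of the deposited data
  (individuals; rarefied stats; normal overlap summaries; kernel overlap
  summaries); CSV output writes one file per table. Column-name mapping on
  input is configurable with documented defaults.
- The CLI is a thin click wrapper over the library; `run` executes the full
  pipeline and writes a JSON manifest (config echo, seed, per-stage counts)
  from which every output is re-derivable.

## Known limitations

- The three published-data checks (individual/species/forest counts, the
  kernel-summary r² values, the paired |Z| values) require the deposited
  individual-level workbook, which is not distributable with this repository;
  the tests that encode them fail with an explanatory message until it is
  placed at `data/deposited_trait_workbook.xlsx`.
- No multivariate (joint leaf size × SLA) overlap, no abundance weighting of
  pairs, no spatial autocorrelation structure, no model selection beyond the
  R² decomposition.
- The Gamma-family mixed model named above as unavailable would be the
  natural robustness check on the log-Gaussian choice.
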