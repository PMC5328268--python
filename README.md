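# itvoverlap

Intraspecific trait variability (ITV) and pairwise trait overlap in woody-plant
communities along a species-richness gradient.

Classic niche theory predicts that as more species pack into a community, each
species' niche — and hence the variability of its functional traits — should
narrow. The alternative is that ITV stays put and co-occurring species simply
become more similar: trait overlap rises with richness. Distinguishing these
patterns takes individual-level trait data (here: leaf size, cm², and specific
leaf area, cm²·g⁻¹) across communities spanning boreal to hyperdiverse
tropical forests (1–284 species/ha), plus estimators that are honest about
wildly unequal sampling effort per species.

This package implements that analysis end to end, for ecologists who have (or
want to simulate) long-format individual trait tables:

- **Rarefied ITV.** For species *i* with trait values *x₁…xₙ* (n ≥ 5), draw 5
  individuals without replacement, compute the coefficient of variation
  CV = 100·s/x̄ (sample sd, n−1), repeat 1000×, and average the replicate
  statistics. Diagnostics: rank stability across draw sizes and CV-by-sample-size
  bins.
- **Trait overlap.** For two species the overlap is the shared area of their
  trait densities, O = ∫ min(f₁, f₂) dx ∈ [0, 1]. Two estimators: a
  closed-form normal-assumption version (intersection points of
  N(μ₁, σ₁²) and N(μ₂, σ₂²) from the log-density quadratic, masses via Φ) fed
  by rarefied moments, and a Gaussian-kernel version (nrd0 bandwidth
  0.9·min(s, IQR/1.34)·n^(−1/5), shared 512-point grid) fed by raw individuals.
  Each forest is summarized by the median pair overlap and the shares of pairs
  with O < 0.25 and O > 0.75.
- **Inference.** A Gaussian mixed model of log CV on species richness, mean
  annual temperature and annual precipitation with a forest-type random
  intercept (Nakagawa–Schielzeth R²ₘ/R²꜀); square-root-transformed OLS of each
  overlap summary on richness; and a paired Wilcoxon signed-rank comparison
  (tie-corrected normal approximation for Z) of the two overlap estimators'
  per-forest medians.
- **Synthetic gradients.** A generator of individual-level datasets under three
  assembly scenarios — constant spacing with a growing trait range
  (`broadening_range`), fixed range with shrinking ITV (`shrinking_itv`), and
  fixed range with constant ITV so species pack closer (`trait_packing`) —
  with analytic expected-overlap profiles as ground truth.

The community metadata of the 21 study forests (type, coordinates, climate,
species richness) ships in `data/forest_metadata.csv`; the synthetic generator
uses the same richness ladder by default.

## Worked example

```bash
python analysis/01_simulate_communities.py
python analysis/02_rarefied_itv.py
python analysis/03_trait_overlap.py
python analysis/04_richness_inference.py
```

The last driver prints (trait-packing scenario, seed 20260924 % 2¹⁶):

```
leaf_size ITV ~ richness (fixed-effects fallback, n=556): slope +0.0001 (p=0.92), R2m=0.004, R2c=0.004
sqrt(median_overlap) ~ richness [leaf_size/normal]: slope +0.00047* r2=0.48 p=0.0014
sqrt(prop_low) ~ richness [leaf_size/normal]: slope -0.00076* r2=0.57 p=0.0003
sqrt(prop_high) ~ richness [leaf_size/normal]: slope +0.00116* r2=0.68 p=0.0000
leaf_size: normal-method medians sit below kernel medians (n=18, |Z|=3.68, p=0.0002)
```

Read: ITV shows no richness trend (the mixed model's richness slope is
indistinguishable from zero and fixed effects explain ~0.4% of variance),
while every overlap summary shifts toward higher similarity in richer forests
— the packed-community signature. The paired test shows the normal-assumption
estimator sits systematically below the kernel estimator at the community
median, so conclusions about the *level* of overlap depend on the estimator
even when the richness trend does not.

The same stages are scriptable via the `itvoverlap` CLI
(`simulate | rarefy | overlap | infer | run | report`), e.g.

```bash
itvoverlap run --preset trait_packing --trait leaf_size --method both \
    --reps 1000 --seed 7 --out results/run7
```

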