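# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `virtualsdm`.

## The synthetic environment

The generator produces V standardized layers over a blob-shaped land mask
whose sample Pearson correlation matrix over masked cells equals a
prescribed target **exactly**. The construction works in the eigenbasis of
the target matrix R = U Λ Uᵀ: each eigencomponent is assigned one smoothed
Gaussian noise field, the fields are Gram–Schmidt orthonormalized over the
mask, and the layers are the mixes X = F (U Λ^{1/2})ᵀ. Because
orthonormalization only ever combines fields of this same construction,
spatial character survives it, and because the component fields are
exactly orthonormal the sample correlation equals R to machine precision.
A plainer alternative — mixing per-layer smoothed fields by a Cholesky
factor — was measured to miss the target by 0.2–0.3 at the smoothness this
study needs (too few independent spatial patches on a finite grid), which
is why the eigencomponent construction is used.

The default `worldclim_like` preset emulates a continental bioclim stack:

- **19 layers**, target correlations built from four variable blocks
  (11/4/2/2 members, within-block r = 0.85/0.92/0.90/0.90, between-block
  0.10–0.35, two layers sign-flipped against their block — analogues of
  temperature seasonality and annual range). The implied eigenvalues are
  (10.56, 3.40, 1.64, 1.46, rest ≤ 0.15): exactly four latent roots above
  one, PC1 ≈ 56% of variance, minor-axis variance totalling 1.94 — the
  canonical published spectrum for such stacks has (10.42, 3.86, 1.71,
  1.14, …) with the same qualitative structure.
- **Grid 200 × 200, blob mask fill 0.6** (~24,000 land cells, matching a
  continental extent at 10 arc-minute resolution). A 150 × 150 grid was
  tried first and rejected: at ~13,500 cells most narrow-tolerance species
  cannot reach the 50 occupied cells the sampling design requires.
- **Multi-scale spatial structure.** The four dominant eigencomponents
  follow slow continental gradients (smoothing scales 0.95/0.65/0.50/0.40
  of the short grid dimension); the minor components vary at 0.11 of it.
  Real climate's dominant axes (latitudinal temperature, continentality)
  vary much more slowly than its residual contrasts; a single common scale
  makes niches collapse to single cells or cover nothing.
- **Clustered heavy-tailed texture.** The minor components additionally
  carry Student-t(3) cell-level noise (amplitude 1 SD) restricted to a
  shared "rough" zone covering ~30% of the map — quiet basins versus
  mountain-belt microheterogeneity. Without it the synthetic world is
  unrealistically smooth at fine scales: 50 occurrence points then cover a
  range's entire environmental extent and envelope methods show almost no
  omission, a regime real climate data do not produce. Injecting the
  texture into the component fields *before* orthonormalization keeps the
  target correlation exact.

What the generator does **not** emulate: true plateau geometry (large
regions of near-identical climate), anisotropy, elevation-driven lapse
structure, and realistic heavy-tailed marginal distributions of
precipitation-like variables. Consequently simulated ranges are smaller
(50–500 cells) and environmental coverage by a 50-point sample is better
than in real continental data; absolute omission rates and range-size
spreads are correspondingly compressed. Passing tests on this world show
the pipeline's mechanics and directional contrasts, not absolute
real-data performance levels.

## Virtual species

A niche is a diagonal Gaussian in the raw layer space:
S(x) = exp(−½ Σ_k (x_k − μ_k)²/σ_k²), σ_k² = f · Var_k(study area),
f = 0.2 (narrow) or 0.6 (wide). S equals 1 exactly at the centroid; no
normalizing constant. Niches are always defined on the raw layers; PCA
sets are a *predictor* treatment only.

Centroids are chosen by k-means (k = 15 by default) on standardized,
spatially neighborhood-averaged environmental vectors; the returned
centroid is the raw vector of the most locally typical cell nearest each
cluster centre (candidates restricted to the half of cells deviating
least from their 2-cell-scale neighborhood mean). The neighborhood
averaging matters once the layers carry heavy-tailed texture: matching on
raw vectors regularly selects isolated texture spikes whose niche matches
no other cell, producing stillborn species rather than biome-core
representatives.

The truth map comes from a colonization–extinction automaton on clamped
suitability p_eff (0 below 0.1, 1 above 0.9, else S):

- initialize at a maximum-suitability seed cell (ties uniform);
- each iteration, every cell occupied at iteration start makes 3 dispersal
  attempts; an attempt draws a jump distance d uniform on {1..5} and a
  target uniform on the Chebyshev ring at exactly distance d — the jump
  distance distribution is part of the protocol, the direction is a
  design choice, and the uniform ring is the simplest geometry under
  which a species can cross up to 4 cells of unsuitable habitat;
- an unoccupied, in-mask target is colonized with probability p_eff;
- afterwards every occupied cell — newly colonized ones included — goes
  extinct with probability 1 − p_eff. Colonization before extinction
  permits rescue effects; a config switch (`extinction_spares_new_colonists`)
  implements the alternative reading.
- 100 iterations by default (measured to be at quasi-equilibrium; an
  optional plateau-stopping rule exists), one realization per species.

The ">0.9 always set to one" clamp is interpreted as certain
colonization-on-arrival and zero extinction, not as unconditional
occupancy irrespective of dispersal — the latter would erase the
dispersal limitation the automaton exists to model.

Species whose final range holds fewer occupied cells than the occurrence
sample size are excluded from the experiment and recorded in the
manifest; with the default conditions this affects 0–2 of 30 species on
typical seeds.

## Algorithms

- **ES (Envelope Score)**: per-variable training min/max; score = fraction
  of variables inside their envelope (values in {0, 1/V, …, 1}).
- **MAHAL (Mahalanobis)**: distance to the presence mean under the
  presence covariance; the inverse switches to the Moore–Penrose
  pseudo-inverse when the reciprocal condition number falls below 1e−10
  (under the pseudo-inverse, duplicating a perfectly collinear variable
  leaves distances invariant — the degeneracy behaviour that matters
  here). Suitability = 1/(1+d); any strictly decreasing transform of d
  gives identical thresholded maps, this one is fixed for reproducibility.
- **LQ_BG**: balanced, L2-penalized logistic regression of presence vs
  background on {x, x²} features standardized by background statistics;
  optional hinge features at background quantiles (off by default). This
  is an honestly-named stand-in for the Maxent-class of regularized
  exponential-family background learners, not a Maxent reimplementation.
- **KERNEL_BG**: RBF-kernel classifier (gamma = 1/(2·bandwidth²·V) on
  background-standardized inputs) via a Nystroem feature map (200
  components) with a balanced logistic link; the decision score is
  min–max rescaled to [0, 1] per prediction surface. Stand-in for C-SVC
  with a radial kernel; the Nystroem approximation keeps a 10,000-point
  background fit tractable on one CPU.

All four share the same fit/predict contract; any object with `predict`
can be plugged into the experiment runner.

## Thresholding and metrics

Binarization is `prediction ≥ t` throughout (required by the LPT
semantics "equally or more suitable"). Two rules:

- **balance**: maximize sensitivity + specificity along the ROC. The ROC
  reference is the *training data* by default (`threshold_ref="train"`:
  scores at the 50 training presences vs the 10,000 background cells) —
  this is what SDM software computes and what a practitioner can do; the
  omniscient variant against the true map (`"truth"`) is available. The
  choice is visible in the results: with training-referenced thresholds
  the envelope's balance and LPT thresholds coincide at score 1.0, so its
  two range-size regressions are identical — the same coincidence the
  benchmark study's range-size table shows. A truth-referenced evaluator
  instead adapts the cut-off to the truth and drives omission of all
  methods to ≈0, erasing the phenomenon under study.
- **LPT**: minimum predicted value over the training presences (zero
  training omission by construction).

Metrics: sensitivity, specificity, TSS = sens + spec − 1,
UP = FN/(TP+FN) (omission), OP = FP/(TP+FP) (the fraction of predicted
presence that is false). The cited source for OP gives no formula;
FP/(TP+FP) is the standard over-prediction rate and behaves correctly
when predicted ranges balloon; the false-positive-rate alternative
FP/(FP+TN) is also computed (`OP_fpr` column). Ratios with zero
denominators propagate as NaN and the affected design cells are dropped
(and counted) by the analyses, never coerced to 0.

## Statistical analyses

- **ANCOVA**: response ~ prevalence + ENV × ALG × TOL with sum-to-zero
  factor coding and Type-II sums of squares (robust to the mild imbalance
  skipped species introduce; Type I/III can be had via `ss_type`).
  Prevalence's share is reported as partial η². A five-algorithm design
  (30 species × 3 predictor sets × 5 algorithms × 10 replicates) leaves
  error df = 4500 − 31 = 4469; the default four-algorithm design leaves
  3600 − 25 = 3575.
- **Stability**: per species × algorithm × predictor set, the sample
  variance of TSS across the 10 occurrence replicates; summarized per
  algorithm × predictor set as the mean across species with a t-based 95%
  CI (tolerance classes pooled).
- **Range-size regression**: OLS of predicted on true range size pooled
  over species × replicates per algorithm × predictor set × rule;
  reports intercept, slope, R².
- **Species residuals**: per-species means (± t-based 95% CI) of the
  TSS-ANCOVA residuals by algorithm and tolerance class — the
  idiosyncrasy diagnostic.

## Reproducibility

Every stochastic stage draws from a named substream keyed by the master
seed plus stage/species/replicate tokens (`rng.substream`), so adding a
species or algorithm never perturbs existing draws, and a config + seed
reproduces the entire evaluation table bit-for-bit.

## Problem sizes

The default experiment (200 × 200 grid, 30 species, 3 predictor sets, 4
algorithms, 10 replicates, 10,000 background cells, both threshold rules)
produces 7,200 evaluation rows in roughly four minutes on one CPU; the
test suite runs the same experiment once for its end-to-end checks.

## Known limitations

- Absolute metric levels are desk-scale: ranges are 50–500 cells and
  prevalences 0.2–2%, versus thousands of cells and up to tens of percent
  in continental data; omission rates of the simple methods (~0.15–0.20
  on raw layers) and range-size R² (0.47–0.91 across groups) are
  correspondingly lower than continental-scale benchmarks (>0.3 and
  ≥0.89), while every directional contrast reproduces.
- Only Gaussian (bell-shaped) niche responses; no biotic interactions or
  temporal environmental change.
- Only uniform random occurrence sampling; no spatial or environmental
  sampling bias.
- The Maxent/SVM stand-ins reproduce the complex-learner class contrast,
  not those tools' exact numerics.
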