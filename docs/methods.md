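# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the known limitations of `pyrocal`. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Calibration model

Each chemical component is modelled independently: the inter-component
correlation analysis (the package's `composition_stats` surface) exists
precisely to check that dependence between components is weak enough for
that to be sensible, with the strongly coupled sugar pair as the known
exception.

### NIPALS PLS

The core estimator is a single-response PLS regression fitted by the
NIPALS sequence. With X (n × p) column-centered and y centered, each step
a = 1…A computes

- weight `w_a = Xᵀy / ‖Xᵀy‖` (unit norm),
- score `t_a = X w_a`,
- loadings `p_a = Xᵀt_a / t_aᵀt_a`, `q_a = yᵀt_a / t_aᵀt_a`,
- deflation `X ← X − t_a p_aᵀ`, `y ← y − q_a t_a`,

and records `SS_a = q_a² · t_aᵀt_a`, the response sum of squares explained
by that latent variable. The regression vector is `b = W (PᵀW)⁻¹ q`. For a
single response no iteration is required; the sequence is exact and
deterministic. The implementation is written out (rather than wrapping a
library) because the VIP screening consumes `w_a` and `SS_a` directly and
latent-variable selection needs predictions of every nested sub-model from
one fit; an independent library implementation serves as a
cross-validation oracle in the test suite instead.

Predictors are mean-centered only — no unit-variance scaling — because all
grid points carry the same physical unit (fraction of dry mass per °C) and
autoscaling would inflate the quiet high-temperature region of the curve
relative to the informative peaks. This is configurable at the data level
(scale X before fitting) but is not the default.

### Latent-variable selection

`select_n_latent` combines two criteria:

1. the cumulative explained response variance `Σ_{a≤A} SS_a / Σ(y−ȳ)²`
   should reach `cum_threshold` (default 0.90);
2. RMSECV(A), estimated by k-fold cross-validation (default k = 10,
   seeded shuffle), should be *relatively small*, operationalized as the
   one-standard-error band: RMSECV(A) ≤ min_A RMSECV + SE(min), with the
   standard error taken across folds at the minimizing A.

The smallest A meeting both is selected; if none does, the RMSECV
minimizer. The one-SE rule is the package's concretization of
"relatively small" — it is the standard conservative choice and avoids a
hard-coded tolerance.

### Comparison models

All comparison models delegate to scikit-learn behind the package's
surface:

- **SVR** — RBF kernel; penalty C ∈ {0.1, 1, 10, 100, 1000}, tube
  ε ∈ {0.01, 0.05, 0.1, 0.3} (on the internally standardized response),
  γ = 'scale'; chosen by seeded k-fold grid search minimizing squared
  error. The response is standardized inside the wrapper because ε is
  scale-dependent and component contents span two orders of magnitude.
- **GPR ensemble** — three independent fits with squared-exponential,
  exponential (Matérn ν = 1/2) and rational-quadratic kernels, each with a
  learned constant prefactor and white-noise term, `normalize_y` on.
  Reported R²/RMSE are the arithmetic mean of the three models' metrics
  (not metrics of a mean prediction). A kernel whose optimization fails is
  dropped with a warning and the ensemble continues.
- **MLR** — ordinary least squares; with p > n this is the minimum-norm
  interpolator, which is the point of including it: it is the natural
  "no regularization" reference that collapses on wide collinear designs.
- **RF** — 200 trees, seeded.
- **SNN** — one hidden layer of width 32, early stopping, seeded
  initialization.

Train/test evaluation uses a seeded shuffle split with test fraction 0.25
(the split rule is a package choice; the test size is `round(n·fraction)`,
so 157 samples give 118/39).

## VIP screening

`VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a )` is the standard
chemometric (Wold) variable importance in projection; `Σ_j VIP_j² = p`
holds identically, so VIP > 1 is "above average". Interval extraction
takes maximal runs of consecutive grid points with VIP > threshold
(default 1.0), merges runs separated by ≤ `merge_gap` (default 5 °C) and
drops merged runs spanning < `min_run` (default 2 °C). The merge/min-run
defaults are artifact choices: pointwise thresholding at 0.1 °C resolution
fragments into slivers that no physically meaningful interval list would
contain. Reported interval sets are always sorted and pairwise disjoint —
overlapping sub-ranges are merged rather than listed separately.

Restricted refitting re-selects the latent-variable count on the reduced
predictor block (its rank differs from the full grid's) and evaluates both
fits on the same split. The headline check is the test-set R² drop
(ΔR² ≤ 0.1 when the intervals carry the signal).

## Preprocessing

Raw thermobalance traces (time, temperature, mass) are converted to DTG
curves by:

1. **Normalization** — mass divided by the reference mass at the end of
   the 105 °C drying hold (the dry mass; water has been removed before the
   ramp), making curves comparable across initial sample masses
   (10.0 ± 0.5 mg nominal). The trace is trimmed to the ramp.
2. **Differentiation** — central differences of normalized mass with
   respect to temperature (one-sided at the ends); the sign convention
   makes mass loss positive. Consecutive duplicate temperatures (hold
   samples) are collapsed by averaging first. Central differences are
   exact for quadratics, which bounds the truncation error at the
   instrument's 1/12 °C ramp sampling far below the noise floor.
3. **Gridding** — linear interpolation onto the uniform analysis grid,
   with a 1 °C edge-extrapolation margin; out-of-span grids raise an error
   naming the offending end.

Optional Savitzky–Golay smoothing of the gridded rate exists behind a flag
and is off by default — the reference protocol reports no smoothing.

Replicate repeatability is quantified by the range-normalized RMSE,
`NRMSE = 100 · RMSE(ref, other) / (max(ref) − min(ref))`, in percent. The
normalization uses the *first* curve's range, so the measure is mildly
asymmetric; pass the reference trial first.

**Grid arithmetic.** The full-resolution grid 105–900 °C at 0.1 °C has
`floor((900−105)/0.1) + 1 = 7951` points. Published descriptions of this
protocol are not internally consistent on this point: an 8436-point count
is sometimes quoted for the same range and step, heating programs that end
at 800 °C are paired with interpolation ranges ending at 900 °C, and
interval lists include ranges above 800 °C. The package honors the stated
range and step (and therefore 7951 points), renders synthetic ramps to the
grid end so round trips are well defined, and leaves the discrepancy
documented rather than resolved.

## Synthetic data generator

The generator emulates the *statistical* structure a 157-sample tobacco
pyrolysis study presents to the calibration — not pyrolysis physics (no
Arrhenius kinetics, heat transfer or char chemistry).

**Compositions.** 19 components with truncated-normal marginals
(illustrative means/spreads typical of flue-cured tobacco; the reference
panel's densities are non-uniform and no public parameters exist, so the
defaults are not calibrated to any dataset). Designated pairs — total vs
reducing sugar (r = 0.95), dichloromethane extract vs solanesol (0.92),
calcium vs refractory acid (0.91) — are coupled by a Gaussian copula,
which controls the Pearson correlation approximately (mild truncation
attenuates it slightly; the construction lands within ±0.05 of the target
at n ≥ 1000).

**Curves.** Each sample's DTG curve is a shared baseline (two
pseudo-biopolymer stages centred at 185 °C and 330 °C plus a small
high-temperature char peak) plus, per component, `content × Σ Gaussian
windows`, plus noise. Gaussians are the simplest smooth unimodal peak —
adequate for exercising a linear calibration, which is all the model
assumes. With zero curve noise the composition → curve map is exactly
affine (superposition holds by construction, and the tests exercise it).
Window positions cluster in 130–470 °C where tobacco constituents
decompose; the three representative components (total phytoaloids,
reducing sugar, total nitrogen) get narrower, better-separated windows,
the rest broad overlapping ones. Peak signal levels give every component a
comparable between-sample curve variance (peak sd 8·10⁻⁵ fraction/°C),
with two deliberate exceptions: the sugars imprint ~1.75× stronger
(sugars dominate stage-1 mass loss) and pH much weaker (acidity barely
moves mass loss directly).

**Noise model.** Two sources, both seeded and reproducible:

- *Curve noise* — band-limited Gaussian noise on the DTG rate: white
  noise smoothed to a correlation length of 8 °C and scaled to a
  per-point sd of 1.6·10⁻⁵ fraction/°C. Differentiated, interpolated
  balance readings are not white in temperature; a few-°C correlation
  length is what instrument noise looks like after the preprocessing
  chain. The magnitude is set so replicate DTG curves disagree by a
  range-normalized RMSE of roughly half a percent, at the good end of the
  repeatability range a well-maintained thermobalance achieves, while
  keeping the peak signal-to-noise ratio of a single component's imprint
  at ≥ 5.
- *Assay noise* — `measure_composition` adds independent Gaussian error of
  0.25 × each component's between-sample sd (≈ 6% relative error on a 20%
  sugar content — typical flow-analyzer reproducibility), clipped to the
  component's bounds. The DTG curves are generated from the *true*
  contents and the models are trained on the *measured* table, so the
  calibration faces a realistic errors-in-variables problem.

This noise structure matters for the model-comparison experiments: with
temperature-correlated curve noise the effective noise rank is comparable
to the training-set size, and the minimum-norm MLR interpolator amplifies
the response assay error catastrophically out of sample, while PLS's
low-rank projection shrinks it away — the qualitative ordering the
calibration literature reports for wide collinear spectra. With white
per-point noise instead, minimum-norm interpolation at p ≫ n is benign
and MLR would *not* collapse; the correlated noise is therefore a modelled
feature of the data, not a numerical convenience.

**Traces.** `render_tga_trace` integrates a DTG curve along a simulated
program — 30 min hold at 105 °C, then 10 °C/min to the grid end, sampled
at 120 readings/min (1/12 °C per ramp reading) — starting from a nominal
10 mg dry mass. The cumulative integral of the piecewise-linear rate is
evaluated exactly at the ramp temperatures, so the render → preprocess
round trip recovers the input curve to ≤ 10⁻³ of the peak rate even on
coarse grids. Replicates add white balance-reading noise (default
5·10⁻⁵ mg per reading).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: nonlinear and interaction effects of composition
on pyrolysis (catalysis, synergy), sample-to-sample variation of the
biopolymer baseline itself, baseline drift and buoyancy artifacts,
non-Gaussian content distributions, and any physical link between a
component's chemical identity and its window positions. A calibration that
passes here has been shown to work *when its own assumptions hold*, no
more.

## Reference experiment designs

`pyrocal.experiments` freezes the three validation designs used by the
test suite and the reproduction script, all on a 1 °C grid (796
predictors, 157 samples, 118/39 split) to keep Monte-Carlo repetition
cheap:

- *Interval recovery* — a study in which only the target component
  imprints (windows 200–260 °C and 330–380 °C, peak SNR ≥ 5); VIP > 1
  extraction is scored by Jaccard overlap against the true windows. With
  the full panel imprinting this experiment would be ill-posed: a PLS
  model must weight interferer windows to orthogonalize against them, so
  VIP > 1 legitimately covers those regions too, and no threshold
  recovers the target's own windows cleanly.
- *Restricted refit* — the same design, comparing full-grid vs
  VIP-interval PLS on one split.
- *Model ordering* — the full default panel; target: reducing sugar.
  PLS (selected A) vs minimum-norm MLR test R² over repeated seeds.

## Numerical choices and degenerate inputs

- NIPALS stops early if the response residual loses all covariance with X
  (weight norm at machine epsilon); requesting more components than
  min(n−1, p) is an error.
- A constant response makes R² (and PLS fitting) undefined — error.
- A constant reference curve makes NRMSE undefined — error.
- Constant composition columns are flagged and their correlations reported
  as NaN rather than silently dropped.
- The pair-correlation matrix for the copula is eigenvalue-clipped to the
  nearest positive semi-definite matrix if overlapping pair constraints
  break PSD-ness.
- Duplicate trace temperatures are averaged before differencing; grid
  interpolation allows a 1 °C edge margin and errors beyond it.
- Seeds: every stochastic step (composition, curve noise, assay noise,
  replicates, splits, CV folds, RF/SNN initialization) derives from an
  integer seed; identical seed + configuration gives byte-identical
  pipeline artifacts.

## Limitations

- The generator's content distributions and window layout are plausible
  but uncalibrated; absolute R²/RMSE values on synthetic data say nothing
  about attainable accuracy on real tobacco.
- Single-response PLS only; multi-response variants are out of scope since
  each component is modelled independently.
- Only hold + single-ramp programs are supported; no baseline or buoyancy
  correction.
- Alternative variable-selection schemes (iPLS, CARS, genetic algorithms)
  are extension points, not implemented.
- The SVR grid is deliberately small; exhaustive kernel-width tuning is
  not attempted.
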