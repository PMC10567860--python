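# Methods

This document describes the statistical model, the synthetic-cohort
generator, the numerical choices behind the implementation, and the known
limitations. Everything stated here is either a property of the code or a
design decision; no empirical claim is made that the package does not
itself compute.

## Problem setting

Post-mortem interval (PMI) estimation from quantified ¹H NMR metabolite
concentrations in pericardial fluid. The statistical difficulties are:

- **Small cohorts.** Forensic autopsy series are small (tens of cases), so
  every multivariate step must be validated by resampling, not asymptotics.
- **Confounding by age.** Subject age correlates with PMI in observational
  autopsy cohorts (older subjects tend to be found later), and many
  metabolites vary with age. A naive regression of PMI on the metabolome
  can therefore exploit age signal rather than decomposition chemistry.
- **Regime change at long PMI.** Above roughly 100 h, bacterial
  co-metabolism produces concentration surges that break the approximately
  linear early-decomposition kinetics, so models are fitted both on the
  full window and on the ≤ 100 h restriction.

## The constrained latent-variable model (`pfpmi.ocpls2`)

The core regressor is a PLS1-type latent-variable model whose score
vectors are forced to be exactly orthogonal to a matrix of constraint
covariates **Z** (here: age).

For each component, the NIPALS weight vector `w ∝ Xᵀy` is projected onto
the null space of `ZᵀX` before normalization, so the score `t = Xw`
satisfies `Zᵀt = 0` **exactly** (to machine precision), not approximately.
Deflation and the regression vector `B = W (PᵀW)⁻¹ q` then follow standard
NIPALS algebra. With zero constraint columns the procedure reduces
exactly to ordinary PLS1 — this reduction is enforced by the test suite
against an independently written textbook NIPALS reference.

Non-predictive ("orthogonal-signal") components may be extracted first;
they capture structured X-variation uncorrelated with y and are filtered
from new samples before prediction.

Internally, `y` is centered and scaled (SD with `ddof=1`); predictions are
returned on the original scale. `X` is expected autoscaled
(`pfpmi.autoscale`: column mean 0, unit SD, `ddof=1`); held-out samples
are scaled with the **training** means/SDs.

What the constraint does and does not guarantee:

- Guaranteed: fitted values and scores carry no linear age signal
  (`corr(ŷ, age) = 0` on training data, up to numerical precision).
- Not guaranteed: that an age-associated metabolite gets a small weight.
  Because the constraint acts on the weight vector rather than on a
  residualized data matrix, the model may *recruit* an age-linked
  metabolite with a non-zero weight precisely to cancel the age component
  carried by the PMI-linked metabolites. Variable-importance scores (VIP)
  of age-linked metabolites can therefore be larger under the constraint
  than without it. Interpret VIPs as "importance to the age-orthogonal
  predictor", not as evidence of a direct PMI link; use the univariate
  profiles and stability selection for marker claims.

### Model selection and significance

- **Component choice** (`select_components`): grid over
  predictive × non-predictive counts (defaults ≤ 2 × ≤ 1), scored by
  repeated k-fold cross-validated Q² (defaults k = 5, 20 repetitions);
  ties break toward the smaller model.
- **Randomization test** (`randomization_test`): y is permuted N times
  (default 999) and the observed R² and Q² are ranked among the permuted
  ones; `p = (1 + #{perm ≥ obs}) / (1 + N)`, so p is bounded below by
  `1/(1+N)` and can never be zero.
- **Reported metrics**: R², Q², SDEC (training RMSE), SDECV
  (cross-validated RMSE), SDEP (held-out test RMSE).

## Stability selection (`pfpmi.stability`)

Identifies metabolites robustly useful for prediction:

1. Draw Bernoulli subsamples of rows *and* columns (default 200
   subsamples, inclusion probability 0.7; undersized masks are redrawn
   with a warning).
2. On each subsample, find the best predictor subset by VIP-guided
   backward elimination scored by cross-validated Q².
3. For each metabolite, compare its selection count against a
   random-choice null: given subsample *i* kept `n_i` candidate columns
   and selected `s_i` of them, a metabolite available in that subsample is
   selected with null probability `s_i / n_i`. The count over subsamples
   is then Poisson-binomial; the one-sided tail p-value is computed by
   exact dynamic programming (no normal approximation), and metabolites
   with `p < α` (default 0.05) are flagged *relevant*.

The DP convolution is O(m²) in the number of subsamples and exact to
floating-point rounding; the test suite checks it against brute-force
enumeration over all 2^m outcomes for small m.

**Known anti-conservativeness.** The null above conditions on the
*observed* subset sizes, which were themselves chosen by optimizing
predictive performance on the same data, and treats subsamples as
independent although they overlap heavily in rows. Both effects inflate
the evidence for metabolites correlated with genuinely predictive ones.
In synthetic cohorts the procedure flags the truly PMI-stable control in
more than the nominal 5–10 % of replicates (measured in the test suite).
Treat the relevance flag as a ranking/screening device, not a calibrated
hypothesis test.

## Univariate profiles (`pfpmi.univariate`)

Per metabolite, a two-factor linear regression of concentration on PMI
and age (`mlr_association`); the reported `r` is the partial correlation
of concentration with PMI given age, consistent with the Frisch–Waugh
partialled regression (asserted in tests). p-values come from the exact
t-distribution of the PMI coefficient; the profile table adds
Benjamini–Hochberg adjusted p-values. `age_correct` returns
age-residualized concentrations for display.

The MLR p-value's type-I error at α = 0.05 is verified by simulation to
lie in [0.03, 0.07] over 1000 null replicates.

## Exploratory PCA (`pfpmi.pca`)

Centered (optionally autoscaled) PCA with Hotelling T² and Q-residual
outlier statistics at nominal 5 % limits (F- and Jackson–Mudholkar-based
respectively). Used for cohort screening before modelling, not for
inference.

## Synthetic cohort generator (`pfpmi.synthetic`)

The generator produces cohorts with known ground truth so that the whole
pipeline can be validated end to end. Defaults mirror the study design the
package targets: n = 24, PMI uniform on 16–170 h, age 20–87 y with
Pearson correlation 0.35 to PMI via a Gaussian copula on uniform margins
(the copula ρ is solved from `r = (6/π) asin(ρ/2)` so the *uniform-margin*
correlation hits the target), 70 % male, and two protein-removal
protocols (U = ultrafiltration, LLE = liquid–liquid extraction) sharing
per-subject latent concentrations but carrying independent technical
noise; ethanol is recoverable only under U.

Per metabolite:

```
structural = baseline + pmi_slope·PMI + age_slope·age
             + surge_slope·max(0, PMI − surge_onset)
latent     = structural · exp(η),  η ~ N(0, ln(1+biological_cv))
observed   = latent · exp(ε),      ε ~ N(0, ln(1+noise_cv))
```

The lognormal biological factor is shared across protocols (so duplicates
stay correlated); the technical factor (default CV 15 %) is drawn per
protocol. Negative values are clipped at zero. Sub-streams of the seed
are fixed per role (metadata / biology / U-noise / LLE-noise), so the
metadata table is reproducible independently of the panel.

The 50-metabolite default panel contains four PMI-linked metabolites
(choline, ethanolamine, glycine rising; hypoxanthine falling), four
late-surge metabolites with hinge onset at 100 h (formate,
trimethylamine, propionate, butyrate), a PMI-stable control
(3-hydroxybutyrate), two exogenous compounds (ethanol, caffeine) excluded
before modelling, and 39 PMI-independent fillers with large (70 % CV)
inter-individual variability. Slope magnitudes were chosen so that the
decomposition products change many-fold across the window while fillers
are dominated by between-subject spread — the generator's point is
realistic *signal-to-cohort-noise structure*, not literal concentrations.

**What the generator does not emulate:** spectral acquisition and
deconvolution (peak overlap, baseline, binning), limits of detection and
censoring, batch/run-order effects, cause-of-death–specific metabolic
states, temperature or body-storage covariates of decomposition rate, and
non-lognormal outliers. Conclusions about those factors cannot be drawn
from simulations with this generator.

## Pipeline (`pfpmi.pipeline`, CLI `pfpmi`)

`run_study` chains the full workflow: load or simulate a cohort → drop
exogenous metabolites → cohort summary → PMI-stratified 18/6 split
(equal-frequency PMI bins with largest-remainder test allocation,
rejection-sampled to balance sex within one subject and mean age within
half a cohort SD) → per protocol and per PMI range (full and ≤ 100 h):
component selection, constrained fit, repeated CV, randomization test,
held-out SDEP, stability selection, univariate profiles. Reports are
JSON + CSV and byte-identical across reruns with the same seed (all
randomness flows from one `SeedSequence`).

## Numerical choices

- All randomness uses NumPy `Generator`/`SeedSequence`; child seeds are
  spawned, never reused, making every published number reproducible.
- SDs use `ddof=1` throughout so autoscaled columns have sample SD 1.
- Linear solves use factorizations (`solve`/`lstsq`), never explicit
  inverses; orthogonality projections are re-applied after normalization
  to keep constraint violations at the 1e-12 level.
- The Poisson-binomial tail is computed by exact DP in float64; pmf terms
  are non-negative by construction and sum to 1 within 1e-12.
- Permutation p-values use the add-one estimator to avoid p = 0.

## Limitations

- n = 24 designs give wide sampling variability in Q²/SDEP; single-split
  SDEP values should be read with the repeated-CV SDECV alongside.
- The stability-selection relevance test is anti-conservative (see above).
- The constraint removes *linear* age dependence only; nonlinear age
  effects can still leak into predictions.
- The restricted ≤ 100 h model is fitted on as few as ~15 training
  samples; component selection there is effectively limited to one
  predictive component.
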