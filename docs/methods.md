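# Methods

This note documents the models, the synthetic observation process, the
numerical choices and the known limitations of the `reefmpa` pipeline. It is
the package's own account of its science; every number quoted here is
computed by the test suite or by `scripts/acceptance.py`.

## 1. Biomass reconstruction from visual-census records

A survey unit is a 500 m² belt transect (50 m line, two 5 m bands). Each raw
record is a count of one species in one size bin. Legal bin labels follow
the standard visual-census scheme: 2.5 cm steps to 15 cm, 5 cm steps to
30 cm, 10 cm steps to 50 cm, 12.5 cm steps above, extended to a configurable
maximum (default 250 cm). True lengths snap to the *nearest* label, ties
broken downward (the conservative size).

Weight per individual is the allometry `W_g = a · L_cm^b` with per-species
coefficients (FishBase-style; the synthetic pool draws `a` around 0.013 and
`b` uniformly in [2.85, 3.15]). The recorded bin **label** is used directly
as `L`: no midpoint rule is recorded with the data, and the synthetic
observation process uses the same convention, so reconstruction is unbiased
by construction rather than by cancellation. A diver-bias length correction
is a pluggable per-species callable, identity by default. Skates and rays
(families on the exclusion list) are removed before any biomass arithmetic.

Transect biomasses are averaged (raw scale) across the transects of a
site/date, and the site/date value is `log10(mean_kg + 0.001)`; the 0.001
offset keeps empty surveys finite at −3. Averaging on the raw scale before
the transform is one of two defensible readings of "averaged across
transects"; it is the one implemented.

## 2. Habitat harmonization

Two recording dialects coexist. Photo-quadrat rows are already 2-D percent
covers (≤ 100 in total) and pass through untouched. In-situ rows score three
structural layers (canopy, subcanopy, substrate) against 50-point quadrats,
so totals can exceed 50 points / 100% cover. Harmonization applies strict
top-down occlusion: the canopy layer is kept in full, the subcanopy is
truncated to the remaining point capacity, then the substrate; categories
within a truncated layer shrink proportionally. Totals ≤ 50 points pass
through as `percent = 2 × points`; totals ≥ 50 emerge summing to exactly
100%. Whether the field protocol reduced lower layers jointly or
sequentially is not recorded; the sequential rule is a documented choice,
and the property tests (never inflate a layer, preserve the 100% bound,
identity below capacity) hold for any input.

The 16 fine categories aggregate onto five broad ones — turfing algae,
sessile invertebrates, sand, canopy-forming macroalgae,
understorey-forming algae — via an explicit mapping table; abiotic
categories (bare rock, cobble, shell grit) are dropped with a logged total.
Covers are then averaged per site/date.

## 3. The random-forest counterfactual

Features are exactly 13 columns: latitude, longitude and 11 ocean covariates
(mean SST plus 10 long-term surface means). SST can be recomputed from a
daily series as the mean over the two calendar years preceding the survey.
Only fished sites train the model (a guard raises on any protected row);
75% of them form the training split, 25% are held out. Hyperparameters
(trees, `mtry` = features per split, minimum leaf size) are tuned by 5-fold
cross-validated RMSE; the winner is refit with bootstrap resampling, and
out-of-bag R²/RMSE, held-out R²/RMSE and a permutation-importance ranking
are reported. Predictions are made everywhere, including in-sample at
fished training sites — the same optimism the benchmark design accepts — and
the model card surfaces OOB vs test gaps so that optimism is visible.
Correlated predictors (SST and latitude, deliberately) are retained: forests
tolerate collinearity and the model is used only for prediction.

## 4. Effect summaries

Per protection level: mean LnRR, s.e.m., normal-approximation 95% CI
(±1.96·s.e.m.; percentile bootstrap behind a flag), and the back-transforms
`percent_of_predicted = 100·10^mean` and `percent_elevation = percent − 100`.
The unrounded mean is back-transformed (10^0.06 = 1.148, reported as 114.8%,
not 114%). Significance between levels is read from CI overlap. The
cross-check estimator compares, per MPA, mean observed log10 biomass inside
against fished sites within a 20 km great-circle radius of any member site;
MPAs without eligible controls are excluded and logged, and the Pearson r
between the two effect columns measures method agreement (0.75 over 84 MPAs
on the default synthetic run).

## 5. Multi-model mixed-effects inference

Continuous predictors are z-standardized (human gravity and distance from
shore log10-transformed first); ordinal physical scores (1–4) are treated as
numeric gradients. A correlation screen warns at |r| ≥ 0.5 but drops
nothing. Every model carries a random intercept for 100 × 100 km grid cells
(IDs from floor-divided sinusoidal equal-area coordinates).

Three suites are ranked separately — biogenic habitat (5 covers), physical
environment (5 variables), anthropogenic (gravity, distance from shore) —
each with protection available as a main effect and with each listed
predictor's protection interaction admissible under the hierarchy rule
(interaction ⇒ both mains). All additive subsets are fitted by **maximum
likelihood** (so likelihoods are comparable across fixed-effect structures)
and ranked by

```
AICc = −2·logL + 2k + 2k(k+1)/(n−k−1),
```

where `k` counts fixed effects including the intercept **plus both variance
components** — stated so the numbers are exactly reproducible. Akaike
weights are `exp(−Δ/2)` normalized; a term's importance is the summed weight
of models containing it. Terms with importance ≥ 0.9 (strict) union across
suites into the reduced set, closed under hierarchy. The global suite fits
all subsets of the reduced set; the top model is the most parsimonious
(fewest parameters) within ΔAICc ≤ 4 of the best, ties broken by lower AICc
— parsimony-first is one reading of the selection rule and is applied
consistently. The top model is refit by REML for reported estimates
(Wald 95% CIs, protection contrasts against the fished reference).

Goodness of fit uses Nakagawa R²: marginal
`σ²_f /(σ²_f + σ²_r + σ²_e)` and conditional
`(σ²_f + σ²_r)/(σ²_f + σ²_r + σ²_e)`, with `σ²_f` the variance of the
fixed-effect linear predictor. Residual spatial autocorrelation is tested
with Moran's I under inverse-distance weights (k-nearest-neighbour weights
configurable; no single scheme is canonical), with a two-sided permutation
p-value (999 seeded permutations by default) around the null expectation
−1/(n−1).

Numerical notes: mixed models are fitted with statsmodels' MixedLM under
BFGS with Powell and conjugate-gradient fallbacks (L-BFGS was observed to
stall on a spurious variance-boundary solution); boundary/singular fits are
flagged but retained in the ranking, mirroring common practice.

## 6. The synthetic study conditions

The generator emulates a temperate-Australian-style survey campaign and its
defaults *are* the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 1000 | survey sites along a ~3000 km coastline |
| `prop_fully_protected` / `prop_partially_protected` | 0.21 / 0.24 | network composition |
| `protection_multiplier_full` / `_partial` | 1.34 / 1.10 | planted biomass multipliers |
| `beta_turf`, `beta_sand`, `beta_depth` | +0.05, −0.05, +0.05 | log10-biomass per s.d. of cover/depth |
| `env_effect_sst` | 0.04 | log10 biomass per °C of mean SST |
| `grid_sd` | 0.05 | s.d. of 100 km grid-cell intercepts (log10) |
| `resid_sd` | 0.15 | site-level residual s.d. (log10) — a free choice; no field estimate pins it |
| `n_species`, `transects_per_site` | 30, 2 | observation process |

True site biomass is `baseline(env) + β·z(turf, sand, depth) +
log10(multiplier) + grid intercept + noise`, where the baseline is linear in
SST with minor contributions from two auxiliary covariates (chlorophyll,
oxygen); the remaining covariates are decoys, giving the forest a learnable
signal and a measurable false-positive surface. Site coordinates follow a
coastline arc spanning ~30.5–43.5° S so the SST gradient is strong enough to
learn; smooth environmental anomalies come from random Fourier fields
(length scales 350–400 km). MPAs are contiguous blocks of 3–8 sites
(block sizes drawn first, then interleaved with fished gaps along the whole
coast), which stresses the grid random effect the way real zoning does.
Depth is uniform on 1–25 m, human gravity log-uniform on 0.57–34 856,
distance from shore log-uniform on 1–60 447 m — the observed field ranges.

The observation process draws Poisson counts per species and transect around
the species' biomass share, lognormal individual lengths (σ = 0.18) snapped
to the legal bins, and a couple of ray species that exercise the exclusion
filter. Expected per-individual weights are computed under the same binning
convention used in reconstruction, so summing reconstructed biomass recovers
the truth up to observation noise (r ≈ 0.99 at defaults).

What the generator does **not** emulate: realistic community composition,
temperature time series, coastline geometry, temporal revisits, or
diver-specific biases. Passing tests therefore demonstrate the estimators'
correctness and calibration under a faithful but simplified data-generating
process — not performance on any real survey database.

### Recovery accuracy and Monte-Carlo spread

At defaults the pipeline's recovered fully-protected elevation centres on
the planted +34% and the partially-protected level on ~110% of predicted,
with a seed-to-seed spread of about ±4 percentage points (measured over
5 seeds: 34.8 ± 4.0 and 107.7 ± 3.8). That spread is irreducible under the
stated conditions — with ~210–240 sites per protected group and site-level
noise of 0.15 log10 units, the group mean alone carries ~2 pp of standard
error, and spatially clustered grid effects and forest shrinkage add the
rest. Property tests that loop over replicates (null calibration, sign
recovery) run at reduced sizes (200–320 sites, trimmed forest grid, reduced
global suite) — sizes chosen so 20-replicate loops stay cheap while each
replicate still has ~50+ sites per group.

## 7. Known limitations

- The counterfactual is an in-sample benchmark for fished sites; its
  optimism is reported, not corrected.
- Tuning folds are plain random, not spatially blocked, so forest skill
  estimates are mildly optimistic under spatial autocorrelation.
- Parsimony-first top-model selection can prefer a smaller model whose AICc
  is up to 4 units worse than the minimum; this is deliberate and
  configurable via the ΔAICc window.
- The Moran's I permutation test treats sites as exchangeable under the
  null; with strong covariate gradients in the residual design this is
  approximate.
- No before/after contrast is attempted: the control/impact comparison is a
  cross-sectional cross-check, not a BACI design.
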