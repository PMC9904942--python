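# Methods

This note documents the statistical procedures implemented in
`salmonsize`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish.

## Age accounting

Age codes use European notation `f.o`: `f` winters rearing in fresh water
(0–3; 0 for river-type fish), `o` years at sea (1–4). Total age adds one
year of embryonic incubation, so a 2.3 fish is six years old. Brood year =
return year − total age. Analyses of mean size and its decomposition are
done by brood year, because age composition and mean size on a brood-year
basis are unaffected by recruitment variation; the covariate model uses
return years, because ocean conditions act on fish by calendar year of
residence.

## Reconstruction by weighted resampling

AL samples are representative of sizes within a (river, year, age,
source) stratum but are not sampled proportional to abundance, so raw
sample means are biased estimates of run-wide means. The reconstruction
draws, for each brood-table cell, `escapement_count` fish from the
river/year/age-matched escapement samples and `catch_count` fish from the
district/year/age-matched catch samples (catch cannot be attributed to
natal rivers within a fishing district). Resampling is with replacement:
brood counts (10⁵–10⁷) vastly exceed sample sizes (10³–10⁴).

The draw is implemented as a multinomial over the eligible pool with equal
probabilities; the output stores each unique sampled fish with its draw
count. This is statistically identical to per-individual resampling and
keeps a multi-billion-fish reconstruction at desk scale. All weighted
statistics are therefore *exactly* equal to statistics on the expanded
individual rows (verified against a brute-force expansion oracle).

Numerical choices:

- Non-integer brood counts (they originate from run reconstructions) are
  rounded by largest remainder within each (river, brood year), so totals
  are conserved to ±1 per age group; ties break by cell order.
- Empty-pool fallback ladder: (1) the river's samples pooled over source,
  (2) district catch samples, (3) drop the cell and record it in the
  coverage manifest. No imputation across rivers: systems with chronically
  missing AL data should be excluded, not borrowed for.
- One `numpy` Generator seeded once; cells are visited in sorted order, so
  a fixed seed reproduces the reconstruction byte for byte.

## Size metrics

All lengths are mid-eye-to-fork millimetres, masses grams. Annual mean
size is the weight-averaged length over all fish in scope — which makes
river means intrinsically weighted by catch vs escapement numbers, and
bay-wide means by relative run sizes. Size-at-age anomalies subtract the
long-term age-group mean (per river for river scope, pooled across rivers
for bay-wide scope); by construction the weight-averaged anomaly over all
years is zero, and anomalies are in mm so they compare directly with mean
size changes.

- CV of size-at-age uses the weighted *population* SD (weights are
  population counts, not a sample).
- The length–weight power law W = aS^b is fit by nonlinear least squares
  on mass residuals; starting values come from a log–log OLS fit, which
  makes convergence deterministic. Fits with a ≤ 0 or b outside (2, 4)
  are rejected as implausible for salmonids. Mass conversion applies the
  fitted law to annual *mean* lengths (not fish by fish); by Jensen's
  inequality this slightly understates mean mass for wide length
  distributions — an accepted, documented bias, matching how bay-wide
  mass figures are usually quoted.
- Selection differentials are escapement mean minus total-run mean length
  per return year: the mean trait value after versus before selection;
  negative when the fishery removes large fish.

## Trend decomposition

Total size change is the difference of unweighted window means (each year
counts once) of annual mean size between an early and a late window
(default width 5 years); the same difference of the annual mean
size-at-age anomaly is the size-at-age contribution; their difference is
the age-structure contribution, an identity that holds to machine
precision because it is computed as the residual. The retrospective
analysis fixes the early window and rolls the late window through the
record. Missing years inside a window are dropped with a warning rather
than failing, because early escapement programs have occasional gaps.

## Covariate model

Return-year bay-wide anomalies are modelled by ordinary least squares on:
same-year sockeye run size; pink and chum abundance lagged 1 and 2 years
(conditions during the last years at sea); winter (Jan–Mar) SST of the
return year near the Aleutians; summer (Jul–Sep) SST of the previous year
in the Bering Sea; summer lake temperature lagged 4 years (the freshwater
rearing period of most returning fish; configurable); selection
differentials lagged 4 and 5 years and their average (one generation, to
probe harvest selection on the parents); and a regime factor splitting at
the 1988/89 North Pacific shift, offered in interaction with the SSTs.

Continuous predictors are standardised over the fitted span and quadratic
terms are squares of the standardised columns (nearly orthogonal to their
linear terms); scalers are stored so coefficients can be back-transformed
to natural units. Model search is exhaustive over term subsets subject to
(i) the collinearity screen — no two predictors with |Pearson r| > 0.5 in
one model; pink vs chum is resolved beforehand by univariate variance
explained, since the two series are strongly collinear by construction —
and (ii) marginality (quadratic only with its linear term, interaction
only with both mains). Ranking is by AIC computed with the Gaussian
log-likelihood convention of statsmodels, so refitting the winning term
set reproduces the reported AIC exactly; AICc is available by flag. Ties
break by fewer terms, then term names, making selection deterministic.
All models within ΔAIC < 2 are reported.

Variance partitioning: the share of predictor P is the drop in R² when
all of P's terms are removed from the selected model and the reduced
model refit. For orthogonal predictors shares sum to the full R²; for
correlated predictors they need not — this leave-one-predictor-out
definition was chosen over averaging-over-orderings (LMG) for
determinism and transparency, since no single partitioning convention is
canonical. Partial effects hold other predictors at their mean and carry
closed-form OLS 95% confidence bands.

## Synthetic worlds

The generator emulates the statistical structure of the real system, not
its biology: no spawner–recruit dynamics, no marine survival, no spatial
movement. Defaults state a Bristol Bay-scale world — seven rivers, brood
years 1960–2014, the four dominant age groups (plus optional 0.3
river-type fish), ~5 M fish per river-year (≈2 × 10⁹ fish in total),
baseline sizes ~505–565 mm dominated by ocean age, σ_within = 35 mm,
AL-sampling fractions ~1.3 × 10⁻³ matching the scale of agency sampling
programs, harvest rate 0.6 with logistic length selectivity. Tests and
the acceptance script run the same model scaled down (fewer rivers/years,
smaller runs) and say so.

Annual mean size-at-age follows
η(y) = trend·(y − ȳ) + Σβⱼcⱼ(y) + Σγⱼcⱼ(y)² + ε_y with centred
covariates cⱼ, and ε_y shared across rivers and age groups — which
reproduces the strong among-age-group correlation of annual size-at-age
seen in real data. Individual lengths are Normal within cells: the
pipeline's statistics are means and distribution-agnostic, so the
simplest testable choice wins. Harvest selectivity is logistic in length
with the overall rate rescaled to the configured harvest rate; catch
samples are drawn from the size-biased conditional density, escapement
samples from its complement. Pink and chum abundances share a common
factor and trend (population correlation ≈ 0.8), recreating the
collinearity that forces the pink-vs-chum screening decision. Monthly
SSTs are a seasonal cycle plus a common AR(1) annual anomaly, so regions
are strongly correlated, as observed.

### The parameter-recovery benchmark

`recovery_world()` injects β_sockeye = −1.5 and β_pink = −2.0 mm per
million fish with quadratic terms, SST effects of comparable size, and
calibrates σ_year so the deterministic part explains ~60% of anomaly
variance over 58 years. Two benchmark-specific settings are deliberate:
abundance variability is ~10 M fish so that, at those coefficient
magnitudes, all injected terms carry comparable signal (with realistic
pink variability of ~10⁸ fish a −2 mm/M effect would dwarf everything
else); and the SST annual autocorrelation is lowered to 0.2 so the two
true seasonal SST predictors are not themselves eliminated by the 0.5
collinearity screen — a requirement of identifiability, not realism.
Recovery is measured as: all four injected covariates enter the selected
model (the quadratic terms are sometimes dropped by AIC at this
signal-to-noise, just as equivalently supported models may drop them in
real analyses), and mean back-transformed coefficients within 2 SE of
truth. At these settings the four covariates are recovered in ~97% of
replicates; demanding all six terms succeeds in ~90%, which is near the
theoretical ceiling for six terms of equal share at R² = 0.6, n = 58.

A green synthetic suite establishes that the machinery is correct and
unbiased under the stated generating model; it does not establish that
real sockeye data satisfy that model (Normal within-cell lengths, shared
annual shocks, linear/quadratic covariate effects), nor does it validate
brood tables themselves, which are inputs.

## Known limitations

- AIC keeps spuriously included predictors at the usual ~16% rate per
  null predictor; the intercept-only model is selected for pure-noise
  responses only ~58% of the time with three candidates. This is a
  property of AIC, not a defect of the search.
- The covariate model assumes i.i.d. Gaussian errors; autoregressive
  error structures are out of scope.
- A single bay-wide length–weight fit is used; spatial or temporal
  variation in allometry is not modelled.
- District-pooled catch samples mix rivers within a district by design,
  mirroring the real impossibility of assigning catch to natal rivers.
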