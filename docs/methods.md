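# Methods

`zooenergetics` implements the energetics workflow used to study captive
mammals whose energy budget is in question — here, a browse-fed arboreal
folivorous marsupial: total energy expenditure (TEE) by the
doubly-labeled-water (DLW) method, diet-side metabolizable energy (ME)
accounting from feed logs and fecal collections, a phylogenetically
controlled allometric comparison, and seasonal intake statistics.  This
note records the models, the parameter choices and their rationale, the
numerical decisions, and the limits of what the synthetic-data tests
demonstrate.

## Doubly-labeled water

The method doses an animal with water labeled with deuterium and
oxygen-18.  Deuterium leaves the body only as water; oxygen-18 leaves as
water and as CO2 (via carbonic-anhydrase exchange), so the difference
between the two elimination rates measures CO2 production.

**Kinetics.** Each isotope's post-dose enrichment series (ppm excess over
the animal's own pre-dose background; analytical replicates averaged
first) is fit by ordinary least squares of `ln(excess)` on time in days —
the slope-intercept method.  The elimination rate `k` is minus the slope;
the zero-time intercept is the back-extrapolated enrichment the dose
would produce if mixed instantly.  With exactly two post-dose samples the
fit is the exact two-point line, so the same estimator serves both a
two-sample and a three-sample protocol.

**Dilution spaces.** The dose delivers `dose_mass × label_fraction /
18.02 g/mol` moles of labeled water; on the excess-ppm scale the pure
label is 1e6 ppm, so the space is `N = label_moles × 1e6 /
intercept_excess` (moles of body water).  This normalization convention
is deliberately the simplest internally consistent one; any alternative
plateau/intercept convention can be swapped in through
`dilution_space_from_equivalent`, which takes the dose strength in
ppm·mol directly.  The two spaces are pooled as
`N = (N_O/1.007 + N_D/1.043)/2`, correcting each isotope's known
overestimate of the true pool.

**Energy.** CO2 production is
`rCO2 = (N/2.078)(1.007 k_O − 1.043 k_D) − 0.0246·N·1.05·(1.007 k_O − 1.043 k_D)`
(the second term removes fractionated evaporative loss; algebraically the
whole expression is `N·gap·0.45540…`), and TEE follows from the
Weir-type conversion `TEE = 22.26·rCO2·(1.106 + 3.94/FQ)` kcal/day.  The
food quotient FQ is the ME-weighted mean of macronutrient oxidation
coefficients (protein 0.8, carbohydrate — fiber plus nonstructural — 1.0,
fat 0.7), bounded in [0.7, 1.0].  Body composition comes from the same
dilution: `TBW = 0.01802·N` kg, fat-free mass `TBW/0.732` (lean-tissue
hydration coefficient), fat mass the remainder of body mass.  A
dilution-derived fat-free mass exceeding the supplied body mass is
flagged, not hidden: it means the mass at dosing differed from the mass
given, and the caller should supply the at-dosing mass.

**Precision and its limit.** The TEE signal is the rate gap
`1.007 k_O − 1.043 k_D`.  Error in each fitted slope is
`≈ √2·σ/Δt` for a two-point fit with log-scale noise σ, independent of
the rates themselves — so the *relative* TEE error scales inversely with
the gap.  For a typical DLW regime (k_D = 0.10, k_O = 0.15 per day; gap
≈ 31% of k_O) 1% enrichment noise yields ≈ 4% median TEE error over the
two-point, 7-day design; that regime is what
`simulate.validation_dlw_scenario` encodes and what the recovery
property test asserts (< 5% median over 500 seeded replicates).  The
female-like default scenario (TEE ≈ 288 kcal/day, N ≈ 325 mol) has a gap
of only ≈ 0.016/day — a consequence of this species' unusually low
mass-specific metabolism — and the same noise propagates to ≈ 12% median
TEE error.  Both figures are recomputed by `scripts/acceptance.py`.
This is a property of the measurement design, not of the software: for
low-metabolism animals, DLW precision requires lower analytical noise or
richer sampling.

## Diet intake, digestibility, metabolizable energy

Feed logs record as-fed mass offered and mass remaining the next
morning per item.  The remainder is corrected for overnight evaporative
loss by dividing by `1 − moisture_loss_overnight` (an item-specific
fraction from drying trials; default 0) before subtraction, and
consumption is clamped to `[0, offered]` with a warning on weighing
inconsistencies.  Dry-matter macronutrient intake is consumption ×
dry-matter fraction × composition percentage, summed over items; total
nonstructural carbohydrate (TNC) is estimated by difference,
`100 − (ash + CP + NDF + CF)`, clamped at 0 with a warning when assays
oversum.

Apparent digestibility is the ratio-of-period-means estimator
`D = (mean intake − mean fecal output)/mean intake × 100` per nutrient,
with the fecal collection days averaged against the concurrent two-week
mean intake.  A mean-of-daily-ratios variant exists for comparison but
is not the default: gut transit decouples a day's feces from that day's
intake, and the ratio of means is the standard marker-free balance-trial
estimator.  Zero intake leaves a coefficient undefined (never silently
0); negative coefficients are kept and flagged.

ME intake per nutrient is fuel value × grams consumed × digestibility,
with fuel values CP 4, TNC 4, NDF 3, CF 9 kcal/g; totals and the
browse/non-browse partition are exact sums, and urinary and methane
losses are not modeled (the coefficients are therefore upper bounds on
truly metabolizable energy).

## PGLS allometry

Interspecific TEE is regressed on body mass on log10-log10 axes (base
configurable).  Residual covariance is the Brownian-motion matrix of
shared root-to-tip branch lengths with off-diagonals multiplied by
Pagel's lambda; lambda = 0 is phylogenetic independence (the fit then
equals OLS, verified to 1e-8), lambda = 1 pure Brownian motion (verified
against a dense-inverse GLS oracle on small trees).  Lambda is estimated
by maximizing the profile log-likelihood (residual variance concentrated
out, `σ² = RSS_V/n`) over [0, 1]: a 21-point grid scan brackets the
optimum, bounded Brent refines it, and boundary values win ties — the
estimate can be exactly 0 or 1.  Numerically singular trial covariances
during the scan score −∞; a singular covariance at the chosen lambda is
a hard error naming the perfectly correlated taxa.  An observation is
reported as `100 × observed/expected` with the expectation
`10^(a + b·log10 mass)`.

Species names are matched to tree tips exactly after
whitespace/underscore normalization; unmatched taxa are a hard error
listing the names.  Subset fits (e.g. one family) are row filters on the
comparative table, not separate code paths.

## Seasonal statistics

Seasons follow the browse-procurement calendar — summer May–July,
autumn August–October, winter November–January (assigned by month, so
the year boundary is immaterial), spring February–April.  Daily ME
intake is compared across seasons with a classical one-way
fixed-effects ANOVA (explicit between/within sums of squares).  All six
pairwise contrasts use the pooled within-group variance and the ANOVA
residual degrees of freedom — the no-covariate equivalent of
estimated-marginal-means contrasts — with two-sided t p-values adjusted
by Benjamini–Hochberg (Benjamini–Yekutieli available).  The compact
letter display uses the insert-and-absorb construction: start from one
class containing all groups, split any class containing a significantly
different pair, absorb subset classes; the result letters every
non-different pair together and no different pair, resolves
transitivity conflicts (a~b, b~c, a≁c ⇒ b carries both letters), and is
deterministic because pairs and letters are ordered by descending group
mean.

No mixed-effects or repeated-measures structure is modeled: each
animal's daily series is analyzed separately, matching the design the
package targets, and day-to-day autocorrelation is ignored — p-values
are anticonservative to the extent intake is autocorrelated.

## Synthetic data: what it does and does not show

Each generator forward-models the corresponding data collection from
explicit truth, with all randomness through seeded `numpy` Generators
(bit-for-bit reproducible).

* **DLW** inverts the analysis chain (pooled space from true TBW,
  per-isotope spaces from a dilution-space ratio of 1.044, k_O solved
  from true rCO2 given k_D) and emits `background + E0·e^(−kt)` with
  multiplicative lognormal noise of given CV.  Zero-noise recovery is
  exact by construction — it validates the algebra and the code, not
  the DLW method's biological assumptions (constant pool sizes,
  no isotope re-entry), which real data can violate.
* **Diet** draws offered masses (Gaussian, truncated at 0) and eaten
  fractions (truncated Gaussian around season-specific means), logs the
  remainder after the item's overnight moisture loss, and produces fecal
  collections as the realized fecal-window mean intake × (1 − retention)
  per nutrient, ash absorbing the dry-matter remainder.  Noiseless fecal
  output makes digestibility recovery exact; the default "female-like"
  year (575 g browse, 150 g greens, 40 g vegetables, 20 g fruit, 8 g
  biscuit offered; autumn browse consumption depressed ~35%; retention
  DM 0.644, CP 0.508, NDF 0.520, CF 0.635, TNC 0.893) lands near 290
  kcal/day mean ME with a strongly detectable autumn dip.  The shipped
  composition table is synthetic and plausible per food class, not assay
  data; absolute ME levels depend on it, seasonal contrasts much less so.
* **Allometry** simulates a birth–death tree (31 extant tips by
  default), drops the uninformative root edge, pads every tip edge by 1%
  of depth so the final speciation event cannot create an exactly
  singular covariance, rescales depth to 1, draws log10 masses uniform
  on [0.01, 50] kg and residuals multivariate normal with covariance
  `σ²·V_λ` (defaults: intercept 2.1, slope 0.59, λ 0, σ² 0.02 — the
  scale of a marsupial TEE dataset).  Parameter recovery (median slope
  bias < 2% over 200 datasets) validates the estimator under its own
  model; it says nothing about misspecification (non-Brownian evolution,
  measurement error in species means).

## Numerical and reporting choices

* Times in days (hours divided by 24 on input); dosing is t = 0;
  enrichment in ppm excess over the pre-dose background.
* kcal→kJ fixed at 4.184; metabolic body weight is mass^0.75.
  Report tables round kcal and kJ to integers, ratios to 3 decimals,
  FQ to 2, digestibility to 1 — matching the precision the quantities
  support.
* CSV interchange is UTF-8, comma-separated, '.' decimal, ISO-8601
  dates; trees are Newick.  Readers validate schemas up front and report
  bad cells with 1-based line numbers.
* GLS solves use Cholesky whitening (no explicit inverses); `lstsq`
  handles the rank-deficient degenerate cases (e.g. constant response).

## Known limitations

* The dilution-space normalization is one convention among several in
  use; comparisons against results computed with another convention
  should go through the ppm·mol-equivalent entry point.
* Digestibility is *apparent* (uncorrected for endogenous fecal losses)
  and ME ignores urinary/methane losses.
* The seasonal ANOVA treats days as independent.
* PGLS supports a single predictor; no tree inference, dating, or
  within-species variance modeling.
* Body-fat percentages are only as consistent as the body mass supplied
  at dosing; discrepant mass/dilution pairs are flagged rather than
  reconciled.
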