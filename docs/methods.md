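# Methods

## The analysis this package implements

A subordinate large carnivore (leopard) shares a reserve with a dominant
competitor (tiger) whose density differs sharply between the reserve's two
sectors and between two sampling years. Three linked questions are asked of
scat data collected under that natural gradient: whether diet composition
shifts away from large-bodied prey under competition, whether faecal
hormone metabolites (fGCM for adrenal stress, fT3M for nutritional status)
track those shifts, and whether habitat productivity (NDVI) co-varies with
either. The package implements each analysis layer as a library module with
a thin CLI, and a synthetic-data module that generates inputs with the
study's published structure, because the original raw data are available
only on request.

## Diet composition

For each study group (area × year cell), species occurrence counts i are
scats containing the species (a scat with two species contributes one count
to each), the denominator j is the total occurrence count, and
RFO = i/j·100. Relative consumed biomass applies the digestibility
correction Y = 1.980 + 0.035·X (X = mean body weight in kg; Y = kg of prey
per collectable faeces) and normalises D = A·Y/Σ(A·Y)·100. Both tables sum
to 100 before rounding by construction; reported percentages are rounded
half-up to 2 decimals at output only.

Size classes follow the published rule large ≥ 60 kg, medium 16–60 kg,
small otherwise; the rule as printed leaves (15, 16) kg unassigned and
60 kg doubly assigned, so we take small = [0, 16), medium = [16, 60),
large = [60, ∞) — no tabulated species falls in the ambiguous zones.
Class-level AFO counts a scat once per class present, so AFO columns may
sum past 100.

The inorganic-matter filter keeps scats strictly below 80% IOM (the
published description is ambiguous at exactly 80%; we discard at the
boundary). Scats without an IOM measurement are treated as not assayable:
excluded from hormone analyses but retained for diet work, which is why the
diet (304) and hormone (203) sample sets differ.

## Rarefaction

Sample-based rarefaction: for t = 1..n, scats are drawn without replacement
(1000 randomizations by default, seeded), occurrences pooled, and the
Shannon index H = −Σ p ln p (natural log, configurable base) averaged. At
t = n the subsample is the full sample, so the curve closes exactly on the
full-sample H with zero spread. No plateau rule was published; ours flags
the first t opening a run of 10 consecutive increments below 0.01 nat,
both knobs configurable.

## Classical tests

Implemented from first principles so their behaviour is fully specified,
with scipy used only for distribution tails; scipy/statsmodels serve as
independent cross-checks in the test suite.

* Pearson χ² with no continuity correction (nothing published suggests
  Yates correction was applied).
* Fisher's exact, two-sided by the probability-mass convention: the sum of
  hypergeometric probabilities not exceeding the observed table's, with a
  1e-7 relative slack — the common software default. The odds ratio is the
  sample ad/bc. The pairwise occurrence comparisons use this test
  (the published table caption names it, overriding a looser mention of an
  "f test" for the same comparisons).
* One-way ANOVA; Tukey–Kramer q for unequal n, with the studentized-range
  CDF computed by nested Gauss–Legendre quadrature (160-point inner rule
  over the range probability, 128-point outer rule over the chi
  distribution of the pooled-SD scale; absolute accuracy ~1e-6, verified
  against an independent implementation).
* Paired t on differences; pooled two-sample t; extra-sum-of-squares F for
  equality of two regression slopes on df (1, nA+nB−4), used by the assay
  parallelism check after linearising to logit(percent bound) vs log dose
  (the standard immunoassay linearisation; the published account does not
  state its transform).

Degenerate inputs (zero margins, zero within-variance, zero-variance
differences, collinear x) are flagged or raised, never silently NaN. When
both regression lines fit exactly (residual SS at floating-point zero), the
slope-equality F is 0 by convention if the common-slope fit is equally
exact, infinite otherwise.

The published overall χ² (8.62) and pairwise p = 0.018 for size-class
frequencies are not reproduction targets: counts reconstructed from the
printed AFO percentages and group sizes give χ² ≈ 6.8, so the exact table
construction behind those statistics is ambiguous; our tests therefore
check the machinery against enumeration oracles instead.

## Gamma GLM for hormone responses

Hormone concentrations are positive with roughly mean-proportional spread,
so log μ = Xβ with gamma errors. Under the log link the gamma IRLS working
weights are identically 1, so each iteration is one least-squares solve of
the working response z = η + (y−μ)/μ; convergence is declared when the
relative deviance change falls below 1e-8 (at most 100 iterations), and a
non-converged fit refuses downstream inference. Dispersion φ is Pearson
χ²/(n−p); standard errors are sqrt(diag((XᵀX)⁻¹)·φ) and coefficient tests
are t on n−p df, matching the convention that prints t rather than z for
gamma fits. Year is coded as numeric calendar year with a West treatment
dummy (East reference) and their interaction — the only coding consistent
with the published intercept/Year magnitudes — and the prey-size factor
takes large as the reference level. When a scat contains several size
classes the largest class present is used (configurable; the published
account does not define multi-class handling).

Nested models are compared by the scaled-deviance F test,
F = (Δdev/Δp)/φ_full on (Δp, n−p_full) df; with an estimated gamma
dispersion the plain χ² LRT is anti-conservative, so the F form is
primary and the χ² statistic is reported alongside. All-pairs group-cell
contrasts on the log scale use single-step adjustment: each contrast's
adjusted p is P(max_j |Z_j| ≥ |z_i|) under the multivariate normal with the
contrasts' correlation matrix, estimated by Monte Carlo (100 000 draws by
default, seeded, MC standard error reported, eigenvalue square root for
the near-singular correlation); Bonferroni is available as a deterministic
fallback, and adjusted p-values are floored at the unadjusted ones. A
model-comparison report ranks candidate term sets by AIC (counting the
dispersion as a parameter) and LRT against the intercept-only null.

## Zonal NDVI statistics

Rasters are plain-text ESRI ASCII grids in a projected metric CRS; the
package never reprojects, and mixing frames is the caller's error. Grids
are 3×3 km cells anchored at the extent origin with partial edge cells
retained and flagged (whether the original analysis kept them is
unpublished, so both behaviours are available by filtering the flag); scat
buffers are exact 2 km circles (area πr² ≈ 12.57 km²; the published
"12 km²" is that figure rounded). A pixel belongs to a zone iff its centre
lies inside the geometry — deterministic and matching common
zonal-statistics defaults; fractional weighting was rejected for
reproducibility. The zonal mean is computed as a shifted mean
(v₀ + mean(v−v₀)), which makes the constant-raster case exact. Zone-level
inference delegates to the classical-test layer: one-way ANOVA with
Tukey–Kramer across named zones per year, paired t per zone across years on
cells matched by id.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (config, seed) using NumPy's PCG64; the
algorithm name is recorded in run manifests.

* **Diet**: per group, each scat draws one species from the group's
  occurrence-probability vector (the published RFO profiles / 100,
  renormalised), or two distinct species with probability 0.102 (the
  published multi-prey fraction); multiplicity is capped at two because
  higher counts were not reported. Group sizes default to the published
  86/76/53/89 identified scats, plus 6/5/7/2 unidentifiable ones to total
  the published 92/81/60/91.
* **Hormones**: gamma responses with mean exp(Xβ) per scat; default β are
  the published coefficient estimates for both hormones, used as sign
  patterns (the within-group variance is unpublished, so the gamma shape
  default of 5 — CV ≈ 0.45 — is a free parameter documented as such).
  Exactly round(121/324 · n) scats are placed at or above the 80% IOM
  threshold (uniform on [80, 100]), the rest Beta(8, 4)-scaled below it,
  so the published filter bookkeeping (203 kept of 324) is reproduced
  deterministically rather than only in expectation.
* **NDVI**: pixels are zone mean + N(0, 0.05) clipped to [−1, 1]; defaults
  put the buffer zone ~0.07 below the other zones and raise all zones by
  0.07 in 2020, mirroring the published contrast pattern (depressed buffer
  zone; year-on-year improvement). A cell-level generator draws per-cell
  means directly at the published per-zone cell counts (135/67/80) so the
  comparison layer reproduces the published df structures.
* **Assay**: dilution curves are linear in logit(response) vs log(dose)
  with configurable slopes; replicate matrices scale the duplicate noise by
  sqrt(π/2) so the duplicate-based CV estimator — biased low by sqrt(2/π)
  at two replicates — is centred on the configured target.

What the generators do **not** emulate: spatial autocorrelation in NDVI or
in scat locations, individual identity or repeated measures across scats,
seasonal structure, assay non-linearity at curve extremes, and any
correlation between diet, IOM and hormone values within a scat beyond the
shared group design. Passing tests therefore demonstrate that the
estimators and tests behave correctly under the study's design and
published marginal structure — not that the original field data would
yield identical numbers. The published hormone-table estimates and the
NDVI F/t statistics are consequently not reproduction targets (raw data
unreleased); they are covered by parameter-recovery, error-rate and
sign-pattern checks instead, and the diet-table biomass cells — which are
fully determined by printed inputs — are reproduced exactly.

## Numerical choices and problem sizes

IRLS tolerance 1e-8 on relative deviance change; studentized-range
quadrature accuracy ~1e-6; Fisher two-sided comparison slack 1e-7
(relative); contrast Monte Carlo 100 000 draws by default (standard error
≈ 0.0016 at p = 0.5, reported per contrast). Error-rate simulations in the
test suite use 1200–2000 replicates for pointwise type-I checks and 500
for the family-wise check, with simulation sizes (n = 60 per LRT
replicate, 4×50 per contrast replicate, n = 2000 for parameter recovery,
150 replicates for the bias estimate) chosen so each check's Monte-Carlo
error is small against the band it asserts. Rarefaction defaults to 1000
randomizations; pipeline configs may lower it for quick passes.

## Known limitations

Fisher's exact reports the sample odds ratio, not the conditional MLE; no
4PL/5PL standard-curve back-calculation; no mixed models for repeated
individuals; no pooled-across-groups RFO mode from printed per-group
tables (per-group denominators are unpublished — pooled summaries are
recomputed from raw scat records only); GeoTIFF and reprojection are out
of scope for raster input.
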