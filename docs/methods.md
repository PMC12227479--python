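# Methods

## The measurement model

Quantification of PEth from a dried blood spot proceeds through extraction of
the spot, addition of a deuterated internal standard (IS, PEth 16:0/18:1-D5;
1 ng absolute, i.e. 20 µL of a 50 ng/mL working solution), LC-MS/MS detection
and integration. The pipeline starts at integrated peak areas; its response
variable is the analyte/IS area ratio.

The synthetic generator assumes a linear detector. For a sample of nominal
concentration C (ng/mL) on a device with actual sampled volume V (µL),
extraction efficiency EE and matrix effect ME, the expected ratio is

    E[ratio] = kappa_a · C · V · EE · ME / (m_IS · kappa_IS)

for any sample that passed through the dried matrix (calibration, QC,
pre-extraction spikes, stability aliquots). Post-extraction spikes skip the
extraction loss (no EE factor) and neat standards in solvent skip the matrix
(no EE, no ME); both use the device's actual volume as reference volume, which
makes the Matuszewski ratio estimators identify EE and ME exactly:

    ME = E[post] / E[neat],   EE = E[pre] / E[post].

kappa_a (counts per ng/mL·µL) and the IS magnitude m_IS·kappa_IS are not
identifiable from any ratio-level statistic; they are free configuration with
defaults chosen only to give realistic absolute area magnitudes.

### Noise

Multiplicative lognormal with unit mean (sigma² = ln(1+cv²), mu = −sigma²/2,
so the realized CV equals the configured one): a within-day factor drawn per
record and a between-day factor shared by all replicates of a
(device, analyte, level, day) cell. The between-day factor is what the
day-wise ANOVA's between-day variance component estimates. The IS area is
drawn with the within-day CV but carries no EE/ME, so the generator's ME
parameter is identical to the ratio-level ME the estimators report. Lognormal
was chosen over truncated normal (also available) because areas are strictly
positive and at the 2–8 % CVs relevant here the two are indistinguishable.

### Device profiles (defaults = study conditions)

| device     | V_actual (µL) | EE   | ME   | cv_within | cv_between |
|------------|---------------|------|------|-----------|------------|
| whatman    | 20            | 0.67 | 1.03 | 0.028     | 0.028      |
| mitra      | 23.7          | 0.57 | 0.97 | 0.040     | 0.040      |
| capitainer | 10            | 0.69 | 0.99 | 0.023     | 0.023      |

EE and ME are per-device means of the reported validation results. The CVs are
set so that simulated repeatability and intermediate-precision RSDs fall inside
the observed per-device ranges (2.2–5.5 % Whatman, 2.4–8.4 % Mitra,
1.4–5.0 % Capitainer); the within/between split is not identifiable from total
RSDs alone and is divided equally — an explicitly arbitrary choice.

Two deliberate modelling decisions:

- **ME is constant across the concentration range by default.** The profile
  type supports a per-(analyte, level-band) ME (bands split at 100 ng/mL), and
  the reported low-level ion suppression for Mitra / PEth 16:0/18:2 (77 % at
  20 ng/mL) can be configured and is exercised in the tests. It is not the
  default because a 21 % response kink inside the calibration range is
  inconsistent with the same study's system-level results (linear calibrations,
  matching-device QC biases ≤ 5 %): level-dependent ME in the generator would
  make those jointly impossible. The defaults therefore form an internally
  consistent parameterization; band-specific ME is a configuration knob.
- **Haematocrit is not modelled.** Real DBS responses depend on haematocrit
  (PEth resides on erythrocyte membranes); the generator assumes the pooled
  blood value throughout. The degradation hook (`degradation_per_h`, default 0,
  area factor (1−r)^t) exists for stability studies but processed samples are
  stable by default.

Consequently, passing tests demonstrate correctness of the estimators and the
transferability logic **under this model** — proportional noise, perfectly
linear response, level-independent ME, no haematocrit or spot-inhomogeneity
effects. They do not certify any real assay.

## Calibration and qualification

The quantification fit is weighted least squares with w = 1/x (also: none,
1/x²), weights normalized to mean 1 — the normalization leaves the
coefficients invariant but keeps the weighted residual SD s_yx on a scale
comparable across weightings. Reported: slope, intercept, weighted correlation
r, s_yx, procedural SD s_x0 = s_yx/|b|, and the unweighted design moments
(x̄, Q_x) that DIN 32645 needs. The weighted form of r is reported (whether
the reference software uses the weighted or unweighted form is not public;
this choice is documented here).

Mandel, Cochran and Grubbs operate on unweighted data, following
DIN 38402-style practice; only the quantification fit is weighted. Cochran
groups are the per-level ratios across the six calibration days. Note that
under a constant-CV noise model the raw-scale Cochran test *correctly* rejects
homogeneity over a 50-fold range (variance grows with level²) — this is
precisely the situation 1/x weighting addresses, and the package reports the
test outcome rather than suppressing it. Critical values are computed from
closed forms rather than hard-coded tables: Cochran via
C_crit = [1 + (k−1)/F(1−α/k; ν, (k−1)ν)]⁻¹ (verified against published tables
in the tests), Grubbs via the t-based bound with α/(2n) allocation. The
outlier screen applies two-sided Grubbs to √w-standardized residuals of the
pooled weighted fit, flags at most one point per invocation, and treats
zero-variance input as degenerate (no outlier).

All qualification tests default to α = 0.01 (99 % significance level).

## DIN 32645 limits

From the unweighted fit of the single-day low calibration (2–12 ng/mL,
m = 6, f = m − 2), with one-sided t at 1 − α and n_future = 1 future
determination:

    LOD = s_x0 · t · sqrt(1/m + 1/n + x̄²/Q_x)
    LOQ: x = k · s_x0 · t · sqrt(1/m + 1/n + (x − x̄)²/Q_x),  k = 3

The LOQ fixed point is iterated from x₀ = 3·LOD to 1e-9 relative tolerance
(error after 100 iterations; in practice convergence takes < 20 because the
iteration map's slope is ≪ 1 for any sane design). Both limits are invariant
to rescaling the response axis. Exactly collinear input degenerates both
limits to 0, which is accepted as the noiseless limit rather than an error.

## Validation metrics

- **ME/EE**: ratio-of-means (not mean-of-ratios), matching the "plot set A
  against set B" convention. The ≤ 25 % scatter criterion is applied to the
  replicate RSD of the numerator set of each estimator (post-spikes for ME,
  pre-spikes for EE); the guideline's "standard deviation" is ambiguous and
  this reading is configurable in principle via the returned raw dispersion.
  The value-band verdict and the dispersion verdict are reported separately.
- **Stability**: drift = 100·(max − min)/mean of absolute analyte areas per
  level, the mean denominator being one reading of "did not differ more than
  x % between each other" (min and first-point denominators selectable). No
  acceptance bound is imposed by default; a threshold is optional.
- **Precision/accuracy**: computed in the concentration domain (QC ratios are
  back-calculated first), because acceptance windows apply to concentrations
  against nominals. One-way ANOVA by day: s_r² = MS_within,
  s_between² = max(0, (MS_between − MS_within)/n_rep), s_I² = s_r² + s_between²
  (the truncation at zero keeps s_I ≥ s_r always). RSD denominators use the
  observed grand mean; bias uses the nominal. For the external certified
  control the certified target serves as the nominal, including in
  cross-device cells.

## Cross-device transferability

Foreign-calibration quantification multiplies each back-calculated
concentration by V_cal/V_sample (= 1 on the diagonal; factors compose along
device chains). Back-calculations outside the calibration range are flagged
but retained in the statistics (no rejection rule is imposed). Under the
generator model the expected volume-corrected relative bias is

    100 · (EE_S·ME_S / (EE_C·ME_C) − 1)

which with the default profiles is ≈ −20 % for Mitra samples on a Whatman
calibration and ≈ +24 % the other way — the systematic under-/overestimation
structure the transferability matrix exhibits. Traffic-light bands follow the
reported table convention on absolute values: < 10 green, 10–15 yellow,
> 15 red; the ±15 % acceptance is inclusive (a cell at exactly 15.0 % passes,
"within ±15 %").

## Problem sizes and determinism

The simulated designs match the study designs exactly (8×6 calibration, 6-point
low calibration, 3+1 QC levels × 8 days × 2, 3×2×5 ME/EE triads, 6-point
stability series). Monte-Carlo summaries use 100–500 replicate simulations,
with replicate seeds drawn from a meta-stream (sequential small integers fed to
the seeding machinery showed mild cross-replicate correlation). Every generator
call is deterministic in (config, seed): repeated full-study runs are
byte-identical, and between-day factors are derived from hashed
(seed, device, analyte, level, day) keys so replicates of a day share them
regardless of generation order.
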