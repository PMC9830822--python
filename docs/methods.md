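# Methods

`milknue` predicts three nitrogen-balance phenotypes of individual dairy cows
— nitrogen use efficiency (NUE, %), nitrogen loss (NL, kg N/d) and the 3-day
moving average of dry matter intake (DMI_a, kg DM/d) — from milk mid-infrared
(MIR) absorbance spectra plus animal covariates. This note documents the
model, the synthetic data the package is exercised on, and the numerical
choices made where the design was genuinely open.

## Trait definitions

For a cow-day record with dry matter intake `DMI_a` (kg DM/d), diet crude
protein `CP` (% of DM), milk yield `MY` (kg/d) and milk protein `P` (%):

    N_in  = DMI_a * CP/100 / 6.25        (kg N/d, feed side)
    N_out = MY  * P/100 / 6.38           (kg N/d, milk side)
    NUE   = 100 * N_out / N_in           (%)
    NL    = N_in - N_out                 (kg N/d)

6.25 is the standard crude-protein-to-nitrogen divisor and 6.38 the milk
protein equivalent. Body-weight change is deliberately neglected: in mid/late
lactation the N flux into or out of body reserves is small relative to milk
N, so NUE here is milk N over feed N, nothing more. DMI enters through a
**trailing 3-calendar-day moving average** (the day and its two predecessors,
averaged over the days actually present); the trailing window was chosen over
a centered one so a record never depends on future days.

Quality control retains records with MY in [5, 80] kg/d, protein in
[2.5, 5.0] %, fat in [3.0, 5.0] %, MUN in [5, 20] mg/dL and DMI_a ≥ 5 kg/d.
Bounds are inclusive (a record exactly on a bound is kept) and applied to
DMI_a, not raw DMI. Engineered covariates: `parity_group` is primiparous iff
parity = 1; `dim_g` bins days in milk every 5 days anchored at day 1
(`floor((DIM-1)/5)`, bin 0 = days 1–5).

## The calibration grid

Six predictor sets x spectra treatments x three algorithms, 48 models per
trait:

| set | predictors                                   | columns |
|-----|----------------------------------------------|---------|
| M1  | masked MIR spectrum                          | 215     |
| M2  | + MY, parity group                           | 217     |
| M3  | + BCS                                        | 218     |
| M4  | + DIM group                                  | 219     |
| M5  | + days in pregnancy                          | 220     |
| M6  | MY, parity, BCS, DIM_g, DIP, protein, fat, lactose, MUN (no MIR) | 9 |

M1–M5 are crossed with {original, MSC, SNV} spectra and {PLS, ridge, SVR}
(45 cells); M6 has no spectra and only the 3 algorithms. `parity_group` is
encoded 0/1 and `dim_g` as a single integer column — the column counts above
force single-column encodings. All predictors and the response are z-scored
(mean 0, SD 1, divisor n−1) on the **training data only**; fitted scalers,
the MSC reference, and all model state are applied unchanged to validation
and external data, so prediction is a pure function of a raw input record.

## Spectral preprocessing

* **Region masking** keeps channels inside four closed wavenumber intervals —
  [968.1, 1577.5], [1731.8, 1762.6], [1781.9, 1808.9], [2831.0, 2966.0]
  cm⁻¹ — discarding water-absorption and noise regions. On the default
  instrument grid exactly 215 channels survive.
* **MSC** regresses each spectrum on a reference (the channel-wise mean of
  the training spectra) and removes the fitted offset and slope:
  `(x − a)/b`. It exactly inverts the scatter model `x = a + b·r`.
* **SNV** centers and scales each spectrum to unit sample SD (divisor n−1).
* Order: **mask first, then MSC/SNV** on the masked vector. The alternative
  order is a one-line config change; results can differ slightly because the
  excluded water regions would otherwise dominate the scatter regression.

## Algorithms

**PLS** is the univariate NIPALS algorithm: each component's weight vector is
proportional to `X'y` (maximal covariance with the residual response),
followed by score computation and deflation of `X` and `y`. The coefficient
vector is `b = W (P'W)⁻¹ q`. The number of latent variables is selected by
cow-wise 5-fold cross-validated RMSPE, stopping at the first component whose
addition does not reduce the RMSPE (cap: 15). Variable importance is the
absolute standardized coefficient |b|, ties broken by column order.

**Ridge** is the closed-form penalized solution with penalty 1.0 by default
(the conventional default of mainstream implementations); penalty 0 recovers
OLS.

**SVR** operates on a 7-component PLS compression of the design matrix
(spectra and covariates compressed as one block). The epsilon-insensitive
RBF support-vector machine is solved in the dual with the bias absorbed into
the kernel (k + 1, i.e. a regularized intercept), which removes the equality
constraint and admits exact coordinate-wise updates — each dual coefficient
is a soft-thresholded, box-clipped Newton step, iterated to a 1e-6 change
tolerance. Defaults: C = 1.0, epsilon = 0.1, kernel width
gamma = 1/(n_features x mean feature variance). Deterministic given the data.

## Validation

* **Within-herd**: cows (never records) of the calibration trial are split
  1:3 test:train, five independent times; all preprocessing and model state
  is refit per repeat; metrics are reported as across-repeat mean (SD).
* **External**: the model fitted on the full calibration trial is applied
  unchanged to the second trial, overall and per diet group.

Metrics: R² (squared Pearson correlation of predictions and truths), RMSPE,
RE = RMSPE / mean of the evaluated truths, and Spearman rank correlation
(mid-ranks for ties). The MSPE decomposes into Theil-type components

    error_bias   = (X̄ − Ȳ)²
    error_slope  = (1 − β)² · mean((X − X̄)²)
    error_random = (1 − R²) · mean((Y − Ȳ)²)

with β the least-squares slope of truths on predictions. With that β
direction and the squared deviation in the random term, the three components
are non-negative and sum exactly to mean((X − Y)²); the random term is
evaluated as the regression residual variance, which is the same quantity
written in a cancellation-proof form. A literal transcription with an
unsquared deviation term would break the identity and can go negative — the
squared form is the only self-consistent reading. Zero MSPE is reported as
percentages (0, 0, 100) and flagged degenerate.

## Applicability-domain diagnostics

Outlier screening projects the calibration spectra onto the first 3 principal
components and flags samples whose squared Mahalanobis distance from the
centroid (PC variances as the metric) exceeds the chi-squared 99.9th
percentile. The degrees of freedom default to the number of PCs — a distance
in k dimensions is chi-squared with k df — and both are parameters.

The **GH (global distance)** of a query spectrum is its squared Mahalanobis
distance in the calibration PC space divided by the number of PCs, with PC
variances computed with divisor n. Under that convention the calibration
set's own mean GH is exactly 1 (an algebraic identity, asserted to 1e-10 in
the tests), so GH reads as "how many calibration-typical distances away".
The applicability analysis uses 5 PCs by default: composition shifts between
diets live partly outside the first 3 nuisance-dominated components, and the
chi-square sampling noise of a group mean shrinks with more components. The
PC count is a parameter everywhere.

## The synthetic trial generator

No public per-cow feeding + MIR dataset exists at this design, so the
package ships a generator whose defaults emulate the two-trial structure the
analysis assumes:

* **T1-like calibration trial**: 60 cows x 10 days = 600 records, one diet
  (CP 17.0% of DM, concentrate:roughage 56:44), production targets MY 32.5
  kg/d, protein 3.4%, DMI 25.2 kg/d.
* **T2-like external trial**: 52 cows x 2 days = 104 records in three
  roughage-level groups (C:R 61:39 / 59:41 / 56:44; 34/34/36 records), with
  lower yields (24.1/24.0/27.1 kg/d), higher protein (3.7/3.7/3.6%) and
  group-graded fat, lactose and MUN reflecting the diet gradient; group 3's
  diet matches the calibration trial most closely.

Production traits come from a latent Gaussian model: value = group mean +
SD x (sqrt(w)·z_cow + sqrt(1−w)·z_day) with w = 0.6 of the variance between
cows and a common 6x6 latent correlation matrix. The matrix and the SDs
(MY 4.5, protein 0.20, fat 0.35, lactose 0.15, MUN 2.0, DMI 2.5) are
generator choices, set so the derived-trait correlation structure matches
what the analysis relies on: MY–N-output correlation above 0.9 (protein
variation modest and uncorrelated with yield), DMI moderately tied to yield
(0.4) and to MUN (0.5, the urea route by which intake reaches the spectrum),
and N intake exactly linear in DMI_a within a diet group (a consequence of
the trait formula, not a tuning knob). DIM is uniform on [154, 452] d
(mid/late lactation), parity is stratified over 1–4 (trials enrol both
parity groups on purpose), DIP derives from DIM minus a uniform open period,
and BCS is a per-cow 1–5 score in quarter steps.

Spectra follow a linear Beer–Lambert-style forward model: each component
(lactose, protein, fat, urea, water) contributes Gaussian absorption bands at
literature-motivated wavenumbers (lactose ~980/1040/1076, protein
~1242/1354/1548, urea ~1160/1460, fat ~1745/1796/2852/2922 cm⁻¹; broad water
bands in the excluded regions), plus a random quadratic baseline, a
per-sample multiplicative scatter factor and offset, white noise, and a
high-variance water amplitude so region masking is consequential. Noise
amplitudes (scatter SD 0.02, offset SD 0.005, baseline 0.005, additive
0.003, water amplitude SD 0.08) are set so that milk composition — not
scatter — dominates the retained-region variance, as in real milk MIR where
the leading principal components carry composition. With noise off the model
is exactly linear: regressing any spectrum on the band profiles recovers the
concentrations to machine precision, which the tests assert.

The instrument grid uses a uniform 3.78 cm⁻¹ step per retained segment,
each anchored at its lower bound, giving 162 + 9 + 8 + 36 = 215 retained
channels, plus filler channels through the excluded gaps, below and above.
The step is the documented choice that reproduces the 215-channel count; it
is a parameter of `make_default_grid`.

**What the generator does not emulate**: lactation-curve dynamics, seasonal
and heat-stress effects, instrument drift between trials, non-linear
component interactions, and real MIR line shapes. Passing tests therefore
demonstrate that the pipeline's machinery is correct and internally
consistent — not that the published accuracy on real cows is reproduced.
Accuracy numbers on the synthetic trials (e.g. within-herd R² ≈ 0.7 for NUE)
are properties of the generator's signal-to-noise choices and are asserted
only as wide sanity corridors and orderings (external ≤ within-herd; GH
grows with diet shift).

## Reproducibility and degenerate inputs

Every dataset is a pure function of its config, including the seed; the
pipeline fans a single seed out to the stages and reruns are byte-identical.
CSV export writes shortest round-trip float representations so
read(write(ds)) is bit-exact. Duplicate (cow, date) keys within a source are
rejected, not averaged. Zero-variance predictors, constant spectra, constant
truths and rank-deficient PC bases raise named errors; within-herd cells
whose training side cannot support a fit are skipped with a logged reason
rather than poisoning the report.

## Known limitations

* NUE/NL ignore body-weight change and urine/faeces partitioning by design.
* The SVR dual with regularized bias is a (standard) variant; its fitted
  intercept behaviour differs slightly from solvers with an exact equality
  constraint.
* The LV-selection rule (first non-improving step) is greedy; a
  one-standard-error rule would pick sparser models.
* Only none/MSC/SNV pre-treatments are implemented; no derivative filters.
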