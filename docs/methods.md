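# Methods

This note documents the statistical model, the numerical conventions and
the design decisions behind `nircal`, in the order the pipeline applies
them. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Spectra are absorbance log(1/R) on a strictly increasing, uniform
wavelength grid, by default 1100–2000 nm in 2 nm steps (451 channels) —
the usable range of a fiber-optic reflectance probe, above which fiber
O-H absorption attenuates the signal. Samples are scanned in triplicate;
replicates are averaged (plain arithmetic mean per channel) before
calibration and prediction. Reference chemistry is a per-sample table of
element concentrations in mg/kg with a below-quantification flag (`Nd`,
LOQ 0.01 mg/kg). Below-LOQ cells are **excluded** from that element's
calibration by default rather than substituted: substituting 0 or LOQ/2
would bias the low-concentration elements (Cu, Ni, Pb) where censoring is
concentrated. Substitution policies (`zero`, `half_loq`) are available as
options on `align`.

## Pretreatments

* **SNV**: per-spectrum centering and scaling to unit SD (n−1
  denominator). Stateless.
* **MSC**: each spectrum is regressed on a reference spectrum by OLS,
  x ≈ a + b·m, and corrected as (x − a)/b. The reference is the mean of
  the *training* spectra only, captured at fit time and reused unchanged
  for prediction; a slope |b| < 1e−12 is an error.
* **Detrend**: subtraction of the least-squares polynomial in wavelength,
  degree 2 by default (the classic SNV-DT convention; degree is a
  parameter). The fit uses a centered/scaled wavelength axis for
  conditioning; the residual is orthogonal to span{1, λ, λ²}.
* **Gap–segment derivative**, four-number code D,G,S1,S2 (derivative
  order, gap, two smoothing segments, all in channels): boxcar smoothing
  with segment S1, then D applications of the gap difference
  Δ(x)(i) = x(i+⌈G/2⌉) − x(i−⌊G/2⌋), then boxcar smoothing with S2.
  Edge channels without full support are **trimmed, not padded** — no
  boundary data is fabricated — and the retained subgrid is propagated so
  downstream wavelength reporting stays correct. For even windows the
  representative channel is forward-biased (index + S//2), mirroring the
  gap's ⌈G/2⌉ convention. `0,0,1,1` is the identity; D ≥ 1 with G = 0 is
  rejected.
* **Composition order**: scatter correction first, derivative second.
  The two are listed jointly in common treatment strings without an
  order; we fix scatter-first as the default (a scatter model is defined
  on absorbance, not on derivative spectra) and expose
  `scatter_first=False` for the other convention.

Treatment strings are parsed case-insensitively with the filler words
"standard"/"only" ignored, so table spellings like `SNV only2,4,4,1`
parse correctly.

## Modified PLS

MPLS is single-response NIPALS PLS with one change: after each factor is
extracted, every column of the deflated spectral matrix is divided by its
residual SD (n−1 denominator) before the next factor is computed. The
per-factor scaling vectors s_f are stored with w_f, p_f, q_f, and
prediction replays the exact training sequence:

    t = x'w_f;  ŷ += q_f t;  x ← (x − t p_f) / s_f

Only the spectral residuals are standardized — the response is not; the
"residuals at each wavelength" phrasing of the method points at X only.
A residual column with zero SD gets scale 1 with a warning. With all
s_f ≡ 1 the algorithm is standard PLS1, and the test suite pins this
equivalence against an independent NIPALS implementation and against
scikit-learn's PLSRegression at 1e−8.

Because every step is affine, the model collapses to a linear form
y = β₀ + Σ βλ·xλ on the pretreated grid. β is accumulated in reverse
through the per-factor maps (O(k·p), no matrix products); the recursion
and the collapsed form agree to numerical precision and that equality is
a standing test. `coefficient_extrema` reports the wavelengths of the
largest |β| with signed values — the standard way these models are
summarized and checked against known absorption assignments.

## Cross-validation and factor selection

Grouped cross-validation with 6 groups by default: a seeded uniformly
random partition (sizes ⌊n/6⌋/⌈n/6⌉, e.g. 11–12 for n = 71), each group
predicted by a model trained on the others. The pretreatment state and
the MPLS factors are refit **inside** every fold; no statistic of the
held-out group leaks into its model. RMSECV(f) pools the held-out
squared errors over all samples at each factor count (plain n
denominator).

Factor selection: global minimum of the RMSECV curve, capped at
`max_factors` = 16 (`factor_rule="min"`). A parsimonious alternative
(`"one_se"`) takes the smallest factor count within one standard error
(approximated as RMSECV·(1 + 1/√n)) of the minimum; it trades a little
RMSECV for flatter, more interpretable regression vectors and is used
when coefficient localization matters.

## Outlier elimination

* **Global H** (spectral): H_i = (1/k)·Σ_f (t_if/s_f)², the Mahalanobis
  distance in standardized score space divided by the number of factors
  k. With sample-SD scaling the training mean is exactly (n−1)/n ≈ 1, so
  the conventional threshold H > 3 is meaningful. H is computed in the
  score space of a PCA retaining 99 % of the pretreated spectral
  variance; elimination is a single simultaneous pass, and an error is
  raised if fewer than 2k samples would survive.
* **T criterion** (chemical): t_i = e_i / SD(e) on calibration residuals;
  |t| > 2.5 is removed and the model refit (including re-running the
  cross-validated factor selection), for at most 2 passes — the threshold
  is standard, the iteration cap is our policy to guarantee termination.
* **Order**: H first (spectral reasons), then T during calibration
  (chemical reasons). The audit trail records every sample's H and t,
  the elimination reason and the pass index, and survivor counts satisfy
  N_final = N_input − |H-removed| − |T-removed| by construction (checked
  by the report's self-audit).

## Assessment statistics

* RMSE uses the plain n denominator throughout (RMSEC, RMSECV, RMSEP);
  RMSEP(C) — the bias-corrected standard error of prediction — uses
  n−1: RMSEP(C) = √(Σ(e−bias)²/(n−1)), giving the identity
  RMSEP² = bias² + RMSEP(C)²·(n−1)/n. The plain-n choice is the one
  under which published external RPD columns reproduce as SD/RMSEP(C).
* R² is the squared Pearson correlation between measured and predicted
  values (cross-validation predictions for the calibration table); the
  1 − SSE/SST variant is computed alongside as `r2_fit`.
* RPD = SD/RMSECV internally, SD/RMSEP(C) externally; > 2 good, < 1.5
  poor.
* Applicability bounds of a calibration: Est.Min = max(0, mean − 3·SD),
  Est.Max = mean + 3·SD of the calibration reference values. External
  validation summaries report the min/max of the *predicted* values
  instead (published external tables do not follow the ±3·SD rule).
* Element correlation matrices are pairwise-complete Pearson (below-LOQ
  treated as missing), p-values from the t transform, cells with < 3
  complete pairs flagged missing.
* `rounded` rounds half away from zero (printed-table convention), and
  `rpd_consistent` checks a printed RPD against printed SD and error
  cells by interval arithmetic over the cell rounding — the correct test
  when every input is itself rounded to one decimal.

## Synthetic data generator

The generator emulates the statistical structure the calibration rests
on, not propolis photophysics.

**Concentrations.** Per region (Chile 52, Galicia 16, Castilla-León 23)
and element, a log-normal truncated to the tabulated range, σ taken as a
quarter of the log-range and μ solved (Brent) so the truncated mean
matches the tabulated mean. Where the lower range end is only a
quantification limit the printed range exaggerates the spread, so the
effective span for σ is capped at 1.5 decades. Dependence is a Gaussian
copula. Two refinements matter:

1. *Pearson targeting*: copula correlation is not Pearson correlation
   after non-Gaussian marginal transforms; each specified pair's latent
   correlation is solved (NORTA-style, bisection on a fixed
   common-random-number sample) so the realized Pearson r hits the
   target.
2. *PD completion, not projection*: only 12 pairwise correlations are
   specified; treating the unspecified entries as 0 gives an indefinite
   matrix, and naively projecting to the nearest PD matrix drags Ca–Mg
   from 0.97 to ≈ 0.93. Instead the free entries are completed by
   alternating projections with the specified entries held exact, which
   succeeds here (minimum eigenvalue floored at 1e−3). The completion
   distance is logged in the truth record.

Within-region correlations therefore match targets closely (the test
suite checks Ca–Mg to ±0.02 at n = 5000 in a single-region draw); pooled
correlations over the three-region mixture additionally contain
between-region mean structure, as in any multi-origin survey. A
configurable fraction of the lowest Cu/Ni/Pb values (6/4/6 % by default)
is censored to `Nd` — left-censoring, as a quantification limit produces —
with the uncensored truth retained in the truth record.

**Spectra.** clean(λ) = fixed organic baseline (slope + water O-H bands
at 1400/1900 nm + a flavonoid band at 1530 nm) + Σ_e c_e·amp_e·shape_e,
where shape_e is a pair of Gaussian bands (width 12 nm, secondary weight
0.6) at the wavelengths where real calibrations localize each element's
regression signal. amp_e = strength_e / SD_e, with SD_e the analytic
population SD, so each element contributes `band_strength` absorbance SD
at its primary band; strengths grade from strong (K 0.10, P 0.07,
Zn 0.06) to weak (Cr 0.007, Ni 0.006). Absorptivity per mg/kg is not a
measurable of the emulated workflow, so the amplitudes are free
parameters recorded in the truth record.

**Why calibrations are imperfect by design.** With band signals far above
instrument noise, a linear model would read concentrations almost
exactly — unlike any real mineral-by-NIR calibration, whose accuracy is
limited by the *indirect* association between element and organic
matrix. The generator therefore makes the spectrum respond to a noisy
proxy of the reference concentration ("organically bound fraction"):
c_spec = c + ε, ε ~ N(0, (a_e·SD_e)²) per sample. The ceiling on
achievable R² is 1/(1+a²); the default a_e grade from 0.23 (K) to ~1
(Cr, Ni), which reproduces the realistic pattern — good calibrations for
K/P/Zn, weak ones for Cr/Ni/Cu — without claiming numeric equality with
any particular survey.

**Measurement artifacts.** observed = m_s·m_r·clean + a_s + a_r +
tilt·z(λ) + white noise, with sample-level scatter (multiplicative
log-SD 0.04, additive SD 0.02, tilt SD 0.004), replicate-level repack
scatter (0.01/0.005), instrument noise SD 0.0015 absorbance per channel,
three replicates. With noise off, SNV and MSC remove the injected
between-replicate scatter essentially exactly (tested at ≥ 95 %
reduction); the noise ladder used in the tests (0.002/0.02/0.1) spans
the floor-dominated to noise-dominated regimes so RMSECV degrades
monotonically.

**What passing tests do and do not show.** The generator shares the
linear-mixture structure, censoring, scatter and replicate design of the
emulated workflow, so end-to-end tests exercise alignment, pretreatment
state handling, elimination bookkeeping and validation statistics under
realistic conditions. It does not model instrument line shape, baseline
chemistry differences between regions, nonlinear matrix effects or real
band assignments; absolute R²/RMSE values on synthetic data say nothing
about any physical instrument.

## Problem sizes and defaults

The default study is the emulated design: 91 samples (52/16/23 by
region), 71 calibration / 20 validation by seeded random split,
triplicate spectra on 451 channels, 6 CV groups, H > 3, |T| > 2.5 with
two passes, max 16 factors, and a 20-treatment grid ({None, SNV, MSC,
Detrend, SNV-DT} × {0,0,1,1; 1,4,4,1; 2,4,4,1; 2,10,10,1}). The full
11-element study including grid search runs in well under a minute on one
core; the acceptance script and test suite use these sizes as-is.

## Known limitations

* The exact internal scaling conventions of commercial MPLS
  implementations are proprietary; this implementation is locked instead
  by its own self-consistency (recursion = collapsed form) and by its
  PLS1 equivalence under unit scalings. Numeric bit-compatibility with
  any vendor tool is not claimed.
* Whether commercial pipelines apply the derivative before or after
  scatter correction is undocumented; the default here is scatter-first
  and configurable.
* The one-SE factor rule uses RMSECV·(1+1/√n) as the SE approximation
  rather than a fold-wise SE estimate.
* PLS regression vectors on correlated spectra are intrinsically
  delocalized; coefficient extrema sit on band centers for parsimonious
  models on the raw grid but can shift to interference-avoiding flanks
  at higher factor counts or after per-spectrum normalization. That is a
  property of the method, not a defect of the implementation.
* Bonferroni-style regional mean comparisons and PLS2/wavelength
  selection are out of scope.
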