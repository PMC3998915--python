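# Methods

`devtempo` measures developmental chronometry in embryo time-lapse
movies: when morphological landmark events happen, whether their
relative timing is invariant across conditions (uniform scaling), and
how the overall tempo depends on temperature.  This note records the
models, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Event catalog and anchors

The catalog (`devtempo.catalog`) lists 36 landmark events of
*Drosophila* embryogenesis in developmental order, from the posterior
gap through hatching.  Two anchors define the internal clock:
*membrane reaches yolk* (completion of cellularization) is the zero
time-point, chosen because it is identifiable precisely in every
species and orientation, and *trachea fills* is the unit time-point.
Eight events — the anchors plus six others recognizable regardless of
embryo orientation — are flagged primary and carry the quantitative
analysis.  Hatching stays in the catalog but is excluded from all
scaling statistics: after dechorionation its timing reflects assay
conditions, and it serves only as a viability indicator.

All frames are 0-based; times in minutes are frame × frame interval;
summaries report hours.

## Thermal model

Total developmental time D (hours between the anchors) follows

    ln D = a + b · g(T)

with two covariate transforms: g(T) = 1/(T + 273.15) (Arrhenius,
inverse absolute temperature — the default, matching the long
tradition of temperature–rate modelling) and g(T) = T in °C.  Both
are straight lines in log duration and over the 10 °C working range
they are nearly indistinguishable in fit quality; the chosen form is
pinned in the fit object and its serialization so results are never
mixed across forms.

Fitting is ordinary least squares on the log scale, restricted by
default to 17.5–27.5 °C: at ≥ 30 °C heat stress slows development
and breaks the log-linear trend, so those points are excluded unless
a species is explicitly fit through 30 °C.  Derived quantities:

* **R²** — 1 − SSE/SST of log durations, identical to the squared
  Pearson correlation between observed and fitted log durations (an
  identity the tests assert).
* **Q10(27.5:17.5)** — D(17.5)/D(27.5); a value of 2.2 means
  development takes 2.2× as long at 17.5 °C as at 27.5 °C.  Reported
  at T_low = 17.5 °C; for the linear-Celsius form Q10 = exp(−10 b)
  independent of T_low, for the Arrhenius form it varies weakly.
* **Rate** — v = 1/D per hour.
* **Prediction interval** — the standard OLS interval for a single
  future observation on the log scale,
  ŷ ± t_{n−2} · s · √(1 + 1/n + (g−ḡ)²/S_gg), exponentiated to
  hours, hence asymmetric on the raw scale.  Requires n ≥ 4.

## Synthetic data generator

`simulate_event_table` realizes exactly the hypotheses the statistics
layer tests.  Each embryo's anchor span is D = exp(a + b·g(T)) · ε
with ε lognormal of unit mean; noise is multiplicative because
durations are positive and the model is fit in log space, where
lognormal noise keeps residuals symmetric.  Each event then falls at
its fixed proportion p_e of the span (pre-cellularization events have
p_e < 0).  Defaults used throughout the tests: duration CV 0.05,
cohorts of 8 embryos per temperature at 17.5–27.5 °C in 2.5 °C steps
— the scale of a per-species condition grid an imaging study of this
kind collects.  The default melanogaster-like law passes through 33 h
at 17.5 °C and 16 h at 27.5 °C.

Because pure duration noise cancels exactly in proportion space, the
generator also exposes `prop_noise_sd`: independent Gaussian jitter
of each non-anchor event's proportion (default 0), modelling
event-calling error.  The anchors stay pinned at 0 and 1.  With
jitter enabled the strict event ordering is only guaranteed when the
jitter is small relative to inter-event gaps; the statistics do not
depend on within-embryo ordering.

The shipped proportion profiles (full 35-event and primary 8-event)
are **illustrative**: the source observations report proportions only
graphically, so the profiles encode realistic spacing and the correct
anchor pins, not measured values.  Per-embryo random streams are
split from the master seed with `SeedSequence` spawn keys
(species, temperature, embryo), so enlarging a cohort never changes
embryos already drawn.

`render_movie` produces toy movies, not photorealistic embryos: an
ellipse embryo whose appearance morphs linearly between
deterministic stage templates (a darkening front sweeping
anterior→posterior, ordering the stages, plus stage-keyed blobs for
correlation contrast), stacked over z with Gaussian blur proportional
to the distance from a drifting true focal plane, plus additive
sensor noise.  Real movies differ in ways the renderer does not
attempt: non-elliptical morphology, internal motion between stages,
illumination drift, debris, and orientation variation.  Passing the
end-to-end recovery tests therefore shows the *pipeline machinery*
(focus selection, windowed correlation calling, statistics) is
correct under the model's assumptions; it does not certify calling
accuracy on real data, which is why the design retains a manual
corrections pass.

## Focus selection

The sharpness score is the classical autocorrelation measure
(Vollath F4) on the mean-centered image: Σ I(x,y)I(x+1,y) −
Σ I(x,y)I(x+2,y).  It is parameter-free, invariant to intensity
offsets, and zero for constant images.  Row-direction only by
default (the classical definition); a `symmetric` flag averages row
and column passes for strongly oriented textures.  Ties break toward
the lower z-index.  Which member of the autocorrelation family the
original acquisition software used is not pinned down; equivalence is
claimed only at the level of "selects the sharpest plane", which the
synthetic stacks verify at ≥ 99% for blur increments ≥ 1 px σ.

## Event calling

Frames are normalized to a canonical raster: Otsu segmentation,
largest component, major axis rotated horizontal, crop to the padded
embryo bounding box, resample to 64×96, orientation resolved by
metadata flags or an asymmetry heuristic (darker half left, darker
half up), and intensities mapped 1st–99th percentile → [0, 1].
Normalization is idempotent and rotation-invariant only up to
interpolation error; tests use correlation tolerances (> 0.97)
rather than exact equality.

Composites are pixel-wise means of same-stage normalized frames; one
bank (in practice built from a single well-annotated species) is
used for all species for consistency.  Each frame is
Pearson-correlated with each composite; zero-variance frames score
NaN and stay NaN through smoothing — missing scores must never turn
into zeros, because a few bad frames would otherwise fabricate or
destroy peaks.  Traces are Savitzky–Golay smoothed, default window
9 frames, order 2: the filter is prescribed by the design, the
parameters are ours — at 1–5 min sampling a 9-frame quadratic spans
short noise bursts without flattening stage transitions.  The event
is the largest interior local maximum (value ≥ both neighbours,
earliest frame on ties) inside a window centred on the proportional
expectation between the two manually supplied anchor frames,
half-width `tol` × anchor span (default tol = 0.10, configurable);
with no interior maximum the window argmax is used.  With the window
spanning the movie and smoothing disabled, the caller provably
reduces to the brute-force argmax of the raw trace.

Corrections come from a CSV (embryo, event, frame) standing in for
interactive review; a correction that breaks developmental order
against neighbouring calls is rejected naming the offending pair.
Correlation peak values are exported with every call; no acceptance
threshold is imposed on them — flagging low-confidence calls is left
to the reviewer.

## Scaling statistics

Proportions p = (t − t_cell)/(t_trach − t_cell) are invariant to any
affine change of an embryo's clock, which the tests verify by
property.  `compare_scaling` runs all pairwise Welch t-tests per
event across groups and Bonferroni-corrects over the whole
event × pair family in one report — the conservative reading of a
blanket correction statement, with the family size recorded in the
report.  Welch rather than pooled variance because condition
variances need not match.  The median/MAD outlier gate (k = 5
SD-consistent MADs; MAD = 0 ⇒ drop everything off the median)
applies to the *reported means and SDs* only, not to the t-tests:
gating before testing measurably inflates the null family-wise rate
at n = 8 (we measured ≈ 0.11 vs the nominal 0.05), while the wide
k = 5 gate on moments still removes only gross mis-calls.

Null calibration is asserted statistically: a calibrated Bonferroni
procedure has true family-wise rate ≈ α, so an empirical rate over a
few hundred replicates fluctuates above α in a large fraction of
runs.  The tests compare the observed rate to the one-sided 99.5%
binomial bound at the replicate count — the check fails only when
the data contradict calibration.  Raw calibration was additionally
verified at 1000 replicates (observed 0.043 at α = 0.05).

`fit_event_predictor` regresses each event's time (hours post
cellularization) on total duration; under exact uniform scaling the
slope equals p_e and intercepts vanish, and the trachea-fill line is
identically slope 1/intercept 0/error 0.  Percent error is the mean
absolute relative residual × 100, so events near the zero anchor
carry large relative errors by construction.

`slope_contrast` targets the heat-stress signature: proportions
regressed on temperature separately below 25 °C and at/above
27.5 °C, slope equality tested per event (Welch–Satterthwaite df on
the two regression SEs), Bonferroni over events.  The contrast is
computed on *proportions*, not raw times: raw event times depend
exponentially on temperature, so two linear regimes of even a
perfectly uniform model would differ in slope, while proportions are
trend-free in both regimes under uniform scaling and acquire a trend
exactly when a stage's share of development changes with temperature
— the phenomenon of interest, in which pre-cellularization stages
take proportionally less and less time as heat stress grows.

## Problem sizes and determinism

The test-suite and acceptance-script simulations use: 50 fit
replicates for Q10 recovery, 200 null replicates for family-wise
calibration, 40 replicates for power, 2000 draws for
prediction-interval coverage, and 20 rendered 300-frame movies
(64×96 px, 3 z-planes) for call recovery — sizes at which every
Monte-Carlo margin is several binomial SEs wide while the whole
suite runs in well under a minute per block.  All randomness flows
from explicit seeds through `numpy.random.SeedSequence`; rerunning
any entry point with the same seed reproduces its output bit for
bit.

## Known limitations

* The renderer's stage appearance is schematic; correlation calling
  on real movies needs real composite banks and retains a manual
  correction pass by design.
* The orientation heuristic (darker half left/up) suits the
  synthetic templates and is overridable per frame via metadata
  flags; real embryos need those flags or a trained classifier.
* Proportion profiles are illustrative defaults, not measurements.
* The thermal model is log-linear only within the non-stress range;
  no thermal-performance-curve (e.g. Sharpe–Schoolfield) machinery
  is provided, and heat-stress points are excluded rather than
  modelled.
* `robust_moments`' MAD = 0 rule discards every value off the median,
  which is aggressive for heavily quantized data (e.g. coarse frame
  intervals).
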