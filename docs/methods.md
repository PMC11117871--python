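# Methods

## Models

A compression half-cycle is described by two parametric curves sharing a
segment-local clock t (seconds, origin at the segment's first sample):

* stress (MPa): σ(t) = C₀ + C₁ / (1 + exp(−C₂(t − C₃))). C₀ is a stress
  offset, C₀ + C₁ the upper asymptote (interpreted mechanically as a
  theoretical ultimate-strength limit), C₂ the exponential scale (s⁻¹), C₃
  the midpoint (s). The derivative at the midpoint is C₁C₂/4; the package
  reports this slope rather than an angle, since an angle would depend on
  axis-scaling conventions.
* stretch (dimensionless): λ(t) = D₂t² + D₁t + D₀, with
  λ = (L − l)/L so λ = 1 at rest and decreases under compression. Note this
  is 1 − engineering strain, not the deformed/original length ratio; the
  package implements the definition as used in the source experiments.

Evaluating both on one grid yields the stress–stretch curve. When stretch
is effectively linear in time (|D₂| ≤ a tolerance, default 1e−3 absolute),
substituting t = (λ − D₀)/D₁ gives a logistic of stretch with C₂′ = C₂/D₁
and C₃′ = D₀ + D₁C₃; this transformation is exact, and the implementation
verifies it pointwise to 1e−12 relative in the tests. The 1e−3 default
separates the observed regimes cleanly: published linear rows have
|D₂| ≲ 3e−2 against their ~0.05–0.46 linear rates, while the genuinely
curved rows (vertebra L5, first cyclic experiment) have |D₂| > 20.
Segments above the tolerance are reported as non-transformable rather than
silently linearized.

Units: stress is treated as MPa (N/mm²) and time as seconds throughout.
The published coefficient tables that seed the reference data do not name
units; MPa/seconds is the consistent reading of the described
instrumentation (forces to 2500 N, areas of order 100 mm²) and is assumed
prominently here.

## Numerical evaluation

The logistic is evaluated through `scipy.special.expit`, which saturates to
the asymptotes for arbitrarily large |C₂(t − C₃)| instead of overflowing —
necessary because near-step fits reach C₂ ≈ 300, for which a naive
`exp` overflows at modest |t − C₃|.

## Segmentation

Stress extrema are found by prominence-based peak picking
(`scipy.signal.find_peaks` on the series and its negation), with defaults
of 5% of the stress range (minimum prominence) and 1% of the trace length
(minimum separation). No extremum-detection parameters are prescribed by
the source procedure, which only displays marked minima/maxima; these
defaults are engineering choices, exposed as arguments and CLI flags.
Flat plateaus resolve deterministically to their first sample. The first
and last samples are eligible as boundary extrema when the head (or a
sufficiently long tail) spans at least the prominence, so the initial
loading ramp — and a monotone ramp-to-fracture — is captured; an abrupt
post-fracture drop shorter than the minimum separation is deliberately
*not* a boundary extremum, so fracture records produce exactly one loading
segment. Detected extrema are forced to interleave strictly (within a
same-kind run the most extreme sample wins, first on ties). Loading
segments run valley→peak and unloading segments peak→valley, sharing the
peak sample so both fits anchor the turning point; cycles are numbered in
time order. The first cycle is fitted like all others by default — real
specimens show adjustment transients there, so exclusion is available as
an option (`exclude_first_cycle`, CLI `--exclude-first-cycle`) but is not
the default.

## Fitting

The logistic is fitted by Levenberg–Marquardt least squares
(`scipy.optimize.least_squares`, analytic Jacobian, ftol = xtol = gtol =
1e−12, up to 20000 evaluations). The initial guess inverts the model's own
structure: C₀ ← min σ, C₁ ← range σ, C₃ ← abscissa of the half-range
crossing, and C₂ from the midpoint-slope relation tan(α) = C₁C₂/4 with the
slope approximated as the range covered over half the span (≈ 8/span),
sign-matched to the trend. This start adapts automatically to both shallow
(C₂ ≈ 1) and near-step (C₂ ≈ 250) segments. On optimizer failure up to 5
restarts are tried from jittered initial points (seeded, 30%
perturbations); persistent failure raises an error carrying the optimizer
diagnostics. No coefficient bounds are imposed by default; bounds switch
the optimizer to a trust-region reflective method.

The logistic family has the exact symmetry (C₀, C₁, C₂, C₃) ≡
(C₀+C₁, −C₁, −C₂, C₃); fits are canonicalized to C₁ > 0, so a falling
(unloading) segment is encoded by C₂ < 0 on forward local time. Published
unloading rows show positive C₂, which is reproducible only under some
unstated segment-local time convention; rather than guess it, the package
documents its own convention and writes the time origin of every segment
into the coefficient table.

The quadratic stretch model is fitted by ordinary least squares on a
scaled-domain polynomial basis (`numpy.polynomial.Polynomial.fit`),
converted back to power-basis coefficients — exact to round-off for
noiseless quadratic data. The direction label follows the sign of the
fitted D₁ ("down" = compression, "up" = recovery). A constant stretch
series is fitted exactly by its intercept and reported with R² = 1, since
the variance-ratio definition is undefined there.

Goodness of fit is R² = 1 − SSres/SStot, hand-implemented from the
defining sums and cross-checked in the tests against an independent
loop-form oracle; a constant observed series raises an error. R² is
reported in the fitted domain (stress–time for time-domain fits,
stress–stretch for stretch-domain fits).

In stretch-domain mode (used for load-to-fracture tests, valid when the
crosshead moves at constant velocity) the logistic is fitted with λ as the
independent variable and the quadratic fit is skipped.

## Uncertainty

Geometry confidence half-widths use t·s/√n with the n−1-divisor sample
standard deviation and the two-sided Student-t critical value at n−1
degrees of freedom (4.303 at df = 2, 95%, computed from `scipy.stats.t`).
The relative stress error is the quadrature sum √((δF/F)² + (δS/S)²). The
stretch error follows the published form δλ = δl/L² verbatim by default;
dimensional analysis of λ = (L − l)/L gives ∂λ/∂l = 1/L, so a
`convention="dimensional"` switch provides δl/L — fidelity first, with the
inconsistency flagged. Default instrument uncertainties in the error
budget are the rated machine precisions: force ±0.1% of the peak reading,
displacement ±0.01 mm.

## Synthetic data

The generators invert the mechanics relations (force = σS, displacement =
L(1 − λ)) from per-segment model pairs and add independent additive
Gaussian noise to stress and displacement. Additive noise is the simplest
model consistent with the near-unity R² of the real tests; the default
noise level used in the noisy tests, 0.5% of the loading amplitude C₁
(≈ 0.036 MPa), is calibrated only to land in that near-0.999 R² regime and
is a synthetic choice, as is the displacement noise of 0.005 mm (half the
±0.01 mm rated machine precision read as ~2 standard deviations).

Consecutive half-cycles are joined continuously by additive offsets (a
C₀/D₀ shift matching each segment's start to the previous segment's end);
the offset-adjusted pairs are attached to the generated record as its
resolved ground truth, so round-trip tests compare against the models
actually evaluated. An optional `max_junction_offset` turns an
unexpectedly large junction shift into an error.

Default cyclic conditions: ten compression–relaxation cycles built on the
published L3 first-cyclic-experiment loading stress coefficients. The
published per-segment coefficients carry no shared time base (their stress
midpoints imply ~6.5 s half-cycles while their stretch rates would then
drive λ far below zero), so the default unloading stress model is the time
mirror of the loading one — the loops then close with no baseline drift —
and the stretch models span λ 1.0 → 0.85 per half-cycle (linear down,
quadratic-with-linear-term recovery up), matching the excursion of the
published loops and giving each loop a genuine enclosed area with a
positive recovery rate D₁. The half-cycle duration is snapped to the 50 Hz
sample grid so segment junctions land exactly on samples; segment-local
clocks then coincide with the generating ones and the noiseless
full-pipeline round trip recovers every generator coefficient to ~1e−13
relative. Default geometry is L = 20 mm, S = 100 mm² (canine lumbar
vertebra scale; the implied peak force ≈ 724 N stays under the 950 N cyclic
test load).

Default fracture conditions: the published L5 load-to-fracture stress row,
run to 12/C₂ past the midpoint (within 2e−4 of the asymptote C₀ + C₁ =
29.03 MPa), followed by an abrupt three-sample drop of 25% of the peak
stress as the fracture marker; stretch falls linearly to 0.8.

What the generators do *not* emulate: viscoelastic creep, progressive
micro-damage (cycle-to-cycle coefficient drift), adjustment transients in
the first cycle, correlated or heteroscedastic sensor noise, and machine
compliance. Passing round-trip tests therefore demonstrate estimator
correctness and pipeline consistency under the assumed model — not that
real vertebrae follow the model; that evidence is the near-unity R² of the
published fits themselves.

## Problem sizes

The default test suite fits 10-cycle traces at 50 Hz (≈ 6 500 samples, 20
half-cycle fits), runs 200-replicate noise studies at 200 samples per
replicate, and 100-replicate R² studies; the whole suite completes in a few
seconds on one core. These sizes were chosen because estimates are already
stable well below them.

## Known limitations

* The stretch-domain transformation is undefined for curved stretch–time
  segments (|D₂| above tolerance); such segments are reported, not forced.
* Published unloading-row sign conventions cannot be byte-reproduced
  without the unstated time origin (see Fitting above).
* R² in stretch-domain mode is not comparable with time-domain R² on the
  same segment; the fitted domain is recorded in the coefficient table.
* Very sharp sigmoids (|C₂| ≳ 50) leave C₂ ill-conditioned even on
  noiseless data unless sampling is dense around the midpoint; recovery
  contracts relax C₂ to 10% relative there.
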