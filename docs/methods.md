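# Methods

## Models

### Derivative EPR lineshapes

CW-EPR records the first derivative of microwave absorption. With the reduced
field x = (B − B₀)/(ΔB_pp/2), the two pure lines are

* Gaussian (inhomogeneous, dipole–dipole broadening):
  Y(B) = e^{1/2}·Y_m·x·exp(−x²/2)
* Lorentzian (homogeneous, exchange-narrowed):
  Y(B) = 16·Y_m·x/(3 + x²)²

Both vanish at B₀, are odd about it, and peak at B₀ ± ΔB_pp/2 with values
±Y_m. The printed sign convention has the positive lobe at B > B₀; spectra
recorded in the opposite detection phase are handled by an `invert` flag that
the deconvolution auto-detects from the order of the raw extrema.

The integral intensity (double integral of the derivative, proportional to
the number of spins) has exact closed forms:
A_G = (e^{1/2}·√(2π)/4)·Y_m·ΔB_pp² ≈ 1.0332·Y_m·ΔB_pp² and
A_L = (2π/√3)·Y_m·ΔB_pp² ≈ 3.6276·Y_m·ΔB_pp². The closed forms are primary;
numeric double integration (which the Lorentzian's 1/x² absorption tail makes
delicate) exists only as a test oracle.

The field axis is millitesla throughout; the reader converts gauss on request
(÷10).

### Deconvolution

A spectrum is fitted as one Gaussian + one Lorentzian (any component list is
accepted for n-component fits) by damped least squares
(`scipy.optimize.least_squares`, method `lm`). Widths and amplitudes are
fitted as logarithms, which keeps the classic unbounded Levenberg–Marquardt
iteration while guaranteeing ΔB_pp > 0 and Y_m > 0. A constant baseline offset
is co-fitted by default; drift and phase errors are out of scope.

The two components share one resonance field B₀ by default — the physical
picture is a single radical population broadened through two channels; an
independent-centers mode exists and the choice is recorded in every result.
Component identity is tracked by shape label from the seeding onward and never
reassigned post hoc.

Seeding: B₀ starts at the zero-crossing between the global extrema, the
Lorentzian at the experimental peak-to-peak width (the narrow component pins
the raw extrema), the Gaussian 3.5× broader at equal integral intensity. If
that seeding converges poorly (correlation < 0.9999 or a collapsed component)
an alternate seeding with the Gaussian carrying the raw feature is tried and
the lower-residual solution kept — this resolves the label-swap local minimum
that otherwise captures single-Gaussian spectra with the Lorentzian.

Goodness of fit is the Pearson correlation between model and data plus the
residual RMS; correlation below 0.99 sets a flag but is not fatal. Collapsed
components (width under two grid steps or amplitude under 10⁻⁶ of the data
peak) are flagged, not errored: a vanishing second component is the correct
answer for a genuinely single-shape spectrum.

g-values use g = h·ν/(μ_B·B₀) with CODATA h and μ_B; per-component g plus an
area-weighted mean are reported, since a one-line summary table prints a
single g per sample.

### Spin quantitation

N_s = N_ref·(I_s·ΔB_s²)/(I_ref·ΔB_ref²) against a DPPH standard. The default
mode uses exactly this raw product, with I_s the half peak-to-peak amplitude
and ΔB_s the experimental width of the raw trace — the single pair of values a
spectrometer report lists. `shape_corrected=True` multiplies each I·ΔB² by its
lineshape area constant, turning the comparison into one of true double
integrals; both modes agree exactly when sample and standard share a shape.
N_ref is a calibration input (default 1.53×10²¹ spins/g for pure DPPH — one
unpaired electron per 394.32 g/mol molecule); every report records the value
used. If a sample mass is present, amplitudes are divided by it; otherwise
they are assumed mass-normalized and a warning is logged. Cavity-Q, filling
factor and temperature corrections are out of scope.

### Power-saturation classification

Each spectrum of a 1–100 mW series is deconvolved, warm-starting from the
previous power so identity follows the shape label. Per component the analysis
collects ΔB_pp(P), the integral intensity A(P) and the amplitude Y_m(P), then
classifies:

* **saturating** — total width increase above `width_slope_tol` (default 5%)
  AND intensity that is non-monotone or grows with exponent b < 0.25 across
  the top power decade;
* **non_saturating** — width stable within tolerance AND full-series exponent
  within [0.4, 1.1]. The band deliberately covers both the ideal CW amplitude
  law (∝ √P, b = 0.5) and growth proportional to the power itself (b = 1),
  since qualitative descriptions of unsaturated lines use either;
* **indeterminate** — anything else, including a series whose intensity never
  grows (identical spectra at all powers).

The top-decade exponent is computed as the log–log secant across P ∈
[P_max/10, P_max] rather than a least-squares slope: below full saturation
A(P) is not a power law, and a regression over the unevenly spaced 1-2-5
power grid is biased upward by that curvature (measured: P_half ≈ 15 mW gives
a regression slope of 0.28 where the true decade growth is 0.17).

### Fluorescence bands

Emission spectra (340 nm excitation) are fitted as two Gaussian bands plus a
constant dark-level offset with bounded least squares (amplitudes ≥ 0, widths
positive), default initial centers 420 and 520 nm. "Half width" is reported as
FWHM = 2√(2 ln 2)·σ — the common spectroscopic reading; an HWHM switch exists
and every result records the convention used. A genuinely single-band spectrum
drives the second amplitude to ~0 and is flagged `collapsed-band`.

### Elemental indices

O/C, O/H and ω = (2·O + 3·N − H)/C from atomic percentages. All three are
projective (invariant under uniform rescaling), so compositions need not close
to 100% — the type accepts a 95–101% sum window by default for ash and
unanalyzed elements. A mass-percent → atomic-percent converter (atomic weights
C 12.011, H 1.008, N 14.007, O 15.999) serves CHN-analyzer users. Report
output rounds half-even to 3 decimals with full precision retained. One
packaged reference sample (RT_3) has ω = 0.02559 computed vs 0.025 tabulated
at the source — a rounding borderline the tests assert within ±0.001 rather
than hide.

## Synthetic data: what it emulates and what it does not

The generators produce composite derivative EPR lines, power series and
two-band emission spectra with additive i.i.d. Gaussian noise scaled to the
clean signal's peak, using `numpy.random.default_rng` (PCG64) so output is
bit-reproducible per seed on any platform.

Preset parameters mirror the two sample families studied: `forest` (g =
2.0024, Gaussian ΔB_pp 1.52 mT, Lorentzian 0.355 mT, A_G/A_L = 2.47) and
`plant` (g = 2.0028, 1.505 mT, 0.45 mT, A_G/A_L = 3.71); fluorescence presets
share centers 420/520 nm with FWHM 101/158 nm (plant) and 87/116 nm (forest).
Component amplitudes are not published anywhere, so the presets reconstruct
them, in one of two modes:

* `area_ratio` (default): Y_m ratio from A_G/A_L via the closed-form areas;
* `experimental_width`: Y_m ratio from a 1-D root search so the composite's
  raw extrema land exactly at the published experimental ΔB_pp (0.38 mT
  forest, 0.46 mT plant).

The two constraints are mutually inconsistent under the shared-B₀ two-
component model (the area-ratio reconstruction implies composite widths of
0.399 and 0.675 mT respectively), which is why both are exposed and each
result records its provenance. Fluorescence preset amplitudes (1.0/0.8 plant,
0.4/0.3 forest) are package choices: published intensity scales are
non-numeric, only the ordering (forest weaker) is constrained.

Saturation series follow the textbook CW laws — homogeneous component
amplitude ∝ √P/(1 + P/P_half)^{3/2} with width ∝ √(1 + P/P_half);
inhomogeneous amplitude ∝ √P at constant width — with P_half = 10 mW by
default. Note the homogeneous *double integral* A ∝ √(P/(1 + P/P_half))
plateaus rather than declines; it is the amplitude that peaks at P_half/2 and
falls. Randomized-ensemble tests draw P_half in 3–15 mW so that saturation is
clearly expressed inside the sweep, matching the observed phenomenology; for
P_half ≳ 20 mW the top-decade exponent stays above 0.25 and the classifier
honestly reports indeterminate.

Not emulated: hyperfine structure, Fe³⁺/Mn²⁺ background signals of real soil
HAs, cavity background, baseline drift, multiplicative or 1/f noise,
field-sweep nonlinearity. A green recovery test therefore establishes
correctness of the estimators under the stated noise model, not robustness to
every instrumental artifact.

## Statistical note on the fluorescence width tolerance

The ±3 nm figure attached to the band half-widths is a reported measurement
uncertainty. At 2% noise the Cramér–Rao bound for the width of the broad,
heavily overlapped 520 nm plant band is ≈ 2.2 nm on the default 0.5 nm axis,
so ±3 nm is a ~1.4σ interval: an efficient estimator must exceed it on a few
percent of seeds (measured: 2 of 40 seed×band draws, median error 0.8 nm).
Ensemble tests therefore assert per-seed center recovery (±5 nm, which holds
with margin) and width-error RMS ≤ 3 nm — consistency with the printed
uncertainty — rather than 100% per-seed coverage.

## Numerical choices

* Optimizer tolerances default to 1e−13 (ftol/xtol/gtol), max 2000 residual
  evaluations; noiseless synthetic spectra converge to residual RMS below
  1e−8 of the peak.
* Spectrum validation requires ≥ 16 strictly increasing field points; the
  parser names the first axis inversion and the offending line of malformed
  files.
* Degenerate (flat) spectra raise a dedicated error before any fitting.
* All physical constants (h, μ_B, g_DPPH, area coefficients) live in one
  module (`humepr.constants`) with CODATA 2018 values.
* Generator configs enforce that the field span covers every component's
  B₀ ± 5·ΔB_pp (the saturation preset sizes the window for the worst-case
  power-broadened width) and that emission axes cover each band's ±3σ.

## Known limitations

* Eq-style quantitation transfers calibration only within one instrument and
  matched acquisition settings; no cavity or temperature corrections.
* The G+L decomposition becomes ill-conditioned when power broadening drives
  the Lorentzian width toward the Gaussian width (strong saturation of weak
  components); curves from such fits carry correspondingly larger scatter.
* Voigt (convolved) profiles, hyperfine multiplets and explicit spin-packet
  convolution are out of scope; the two-component sum is the model.
* T₁/T₂ extraction from saturation curves is not attempted; classification is
  phenomenological.
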