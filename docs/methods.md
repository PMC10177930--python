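# Methods

`sfdikit` quantifies how deep spatially modulated (sinusoidal) illumination
samples a turbid medium such as apple flesh, and how that depth limits the
detection of subsurface features (bruises) in spatial-frequency domain
imaging (SFDI). This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic scenes do and
do not emulate.

## Units and conventions

Lengths are mm, attenuation coefficients mm⁻¹, spatial frequencies
cycles·mm⁻¹. Wavelengths (nm) label property rows and are never operands.
Rasters are row-major `[row, col]`, 0-based; the modulation axis runs along
columns with physical x = col·pixel_pitch and phase referenced to column 0
(a global phase is immaterial — demodulation is phase-insensitive, and this
is tested).

## Diffusion-theory depth formulas (`optics`)

For a semi-infinite medium the effective attenuation is
μ_eff = √(3 μ_a (μ_a + μ_s′)) and the diffuse penetration depth δ = 1/μ_eff.
Under modulation at spatial frequency f the scalar photon-density wave
attenuates with μ′_eff = √(μ_eff² + (2πf_x)² + (2πf_y)²), giving the
effective penetration depth δ′_eff = 1/μ′_eff, which reduces to δ at f = 0
and decreases strictly with frequency. Sub-surface fluence decays as
φ(z) = φ₀ k e^(−z/δ) in the diffusive regime. These are asymptotic
diffusion results: they overestimate the depth actually interrogated in a
backscattering geometry, which is why the Monte Carlo sampling-depth
statistic below exists.

Degenerate inputs (μ_a = 0, or μ_a = f = 0) make these depths infinite;
the functions raise `NonFiniteDepthError` instead of returning overflow
values. A pure absorber (μ_s′ = 0) is admitted in the container because the
depth formulas remain well defined there; the reflectance models, which
need scattering, reject it.

### Defaults for unprintable parameters

* **Anisotropy g = 0.9.** With the published flesh ranges
  μ_a ∈ [0.01, 0.05] and μ_s ∈ [9, 28] mm⁻¹, g = 0.9 simultaneously
  reproduces the 1.50–6.00 mm penetration-depth window and a ≈100 µm mean
  free path (1/(μ_a+μ_s)) — both standard figures for apple flesh. It is a
  parameter everywhere, never hard-coded into a formula.
* **Refractive index n = 1.35**, typical for fruit flesh; used only by the
  boundary-sensitive models (Fresnel reflection in the Monte Carlo,
  boundary mismatch A in the diffusion reflectance), not by the depth
  formulas.

The packaged table `data/apple_optical_properties.csv` carries the six
integrating-sphere rows (550–730 nm) of peeled 'Golden Cream Delicious'
flesh. No wavelength interpolation is offered: only the six printed rows
plus user-supplied values.

## Three-phase demodulation (`demodulation`)

Patterns I_p = I_DC + I_AC·cos(2πf_x x + φ_p) with φ_p ∈ (−2π/3, 0, +2π/3)
demodulate as I_DC = (I₁+I₂+I₃)/3 and
I_AC = (√2/3)·√((I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²). On noiseless synthetic
patterns this round trip is exact to machine precision (asserted at 1e−12).
Flat-field correction divides by a reference (whiteboard) image and scales
by its calibrated reflectance (0.99); the AC channel is corrected only when
the reference carries AC content at the same frequency, since a planar
reference has none. 8-/16-bit integer images are promoted to floats in
[0, 1] on read; quantization is modeled only by the scene generator.

Two frequency sets are packaged: the 18-value sweep
[0.01:0.01:0.15, 0.20, 0.25, 0.30] mm⁻¹ used for the buried-hole phantom
and {0.05 … 0.30} mm⁻¹ in 0.05 steps for the covered-target and bruise
studies. The projector-to-sample pixel pitch is always an explicit input;
there is no physically meaningful default.

## Monte Carlo sampling depth (`mc`)

Standard variance-reduced photon random walk (MCML-style): pencil beam into
+z, step s = −ln ξ/μ_t, fractional absorption w·μ_a/μ_t per interaction,
Henyey–Greenstein scattering with anisotropy g, unpolarised Fresnel
reflection at z = 0 for relative index n (specular reflection of the
incident beam is debited at launch), Russian roulette below weight 1e−4
with survival probability 0.1. A two-layer medium (distinct top layer over
a semi-infinite bulk) is supported; both layers share the bulk's refractive
index, so the external surface is the only index mismatch. A top layer
identical to the bulk is collapsed to the semi-infinite path — physically a
no-op boundary — which also keeps the random stream identical, an invariant
the tests assert bitwise.

The weight ledger `launched = specular + exited + absorbed + termination
residual` closes to float accuracy on every run. Two details make that
possible: the residual is the *net* roulette weight (kills minus survival
boosts — a gross kill tally cannot balance, because surviving photons are
boosted by 1/p), and the absorbed tally is Kahan-compensated over the ~10⁸
additions of a large run. A per-photon step cap (default 10⁶, configurable)
guards the μ_a = 0 limit, where the surface first-passage time of the walk
has infinite mean; capped weight joins the termination residual, and the
cap is never approached for absorbing media (typical walks are < 10⁴
steps).

**Frequency-resolved reflectance.** Each escaping photon is recorded with
exit weight w_i, exit radius ρ_i and deepest visited depth. For radially
symmetric reflectance, the spatial-frequency-domain reflectance is the
zeroth-order Hankel transform, estimated photon-wise:
R(f) = Σ w_i·J₀(2πf ρ_i)/N. This is a self-contained equivalent (exact in
expectation) of tabulated scaled-Monte-Carlo lookup approaches, and it is
cross-checked in the tests against a radially binned transform of the same
records and against the diffusion forward model (agreement within 10% in
the high-albedo regime).

**Sampling depth.** The depth quantile at fraction q is the smallest
maximum-visit depth below which a fraction q of the frequency-weighted
detected light stayed — the depth enclosing the photon trajectories
responsible for that share of the detected signal. At high frequency the
signed J₀ weights can make R(f) tiny or negative; the quantile routine
refuses frequencies with R(f) ≤ 0.05·R(0) rather than report statistics
from an oscillatory CDF. Headline depth numbers use f = 0 (planar
illumination); a frequency sweep is available and the quantiles shrink
with frequency, the depth-resolved property of SFDI.

With the packaged table, g = 0.9, n = 1.35, 10⁶ photons: the 550 nm
25%/75% quantiles land near 0.6/2.0 mm and the deepest wavelength's 75%
quantile near 2.3 mm — i.e. the detected light essentially never
interrogates deeper than ≈2.2 mm of flesh, far shallower than the 2.9 mm
diffuse δ at the same properties. Default seed 20230425; per-wavelength
runs derive independent sub-seeds.

## Forward model and inversion (`inversion`)

Diffusion reflectance of a modulated plane wave:
Rd = 3A a′/((μ′_eff/μ_tr + 1)(μ′_eff/μ_tr + 3A)) with μ_tr = μ_a+μ_s′,
a′ = μ_s′/μ_tr, A = (1−R_eff)/(2(1+R_eff)),
R_eff = 0.0636 n + 0.668 + 0.710/n − 1.440/n². Rd ∈ (0, 1], equals 1 only
in the perfect-albedo planar limit, and decreases strictly with frequency
and absorption.

Inversion is two-frequency: Rd at DC and at 0.1 mm⁻¹ by default (both
inside the experimental sets; which pair an instrument uses is a free
choice). A 256×256 log-spaced table over μ_a ∈ [0.001, 0.5] and
μ_s′ ∈ [0.1, 5.0] mm⁻¹ is searched per pixel by nearest neighbour in
(Rd₁, Rd₂) space (k-d tree), followed by one damped Newton step on
(log μ_a, log μ_s′) with finite-difference Jacobians, clamped to one cell.
The cell pitch is ≈2.5%/1.6% in μ_a/μ_s′, so even the unrefined lookup is
within the recovery tolerances; the Newton step brings uniform noiseless
round trips to ~0.1%. The residual map is the reflectance-space distance to
the forward model at the recovered properties; pixels with residual > 0.02
or queries outside the table's reflectance range are flagged invalid.
Build time checks invertibility by the sign of the Jacobian determinant of
the grid mapping and warns listing degenerate cells.

Measured images are converted to reflectance against a reference target:
Rd_sample = I_sample/I_reference · Rd_model(reference properties) per
channel. The canonical reference is a 99%-reflectance whiteboard; its
effective properties are obtained by solving the forward model for the
μ_a (at μ_s′ = 2 mm⁻¹) that yields Rd(0) = 0.99, rather than hard-coding
numbers.

## Contrast metrics and the penetration rule (`contrast`)

Michelson contrast uses the raw ROI extremes (no percentile clipping — an
optional future flag; the raw definition is the documented one). The PVR
profile is the ROI mean across the bar axis. A 3-sample moving mean is
used only to *locate* extrema (sign changes of first differences, plateaus
collapsing to their first sample); each peak/valley intensity is then read
from the raw profile as the local max/min inside the smoothing window, so
smoothing steadies detection without biasing amplitudes (a moving mean
would otherwise damp — and for bar periods at the sampling limit even
parity-flip — the extrema). I_peak/I_valley are means over all detected
extrema; if smoothing flattens every extremum, detection falls back to the
raw profile. Constant profiles raise a degenerate-profile error.

The penetration rule declares a slice penetrated when PVR ≥ 1.2 (threshold
configurable; ties count as penetrated) and reports the largest penetrated
thickness. The rule is monotone in the threshold. A non-monotone series —
possible with noise near the threshold — warns and uses the last
up-crossing. The companion linear fit of contrast vs thickness defaults to
the 0.9–2.5 mm window where the decay is approximately linear.

## Synthetic scenes (`scenes`)

Scenes assign per-pixel effective properties, evaluate the diffusion
forward model per channel (DC at f = 0, AC at the pattern frequency), and
attenuate the reflectance contrast of a structure buried at depth z by the
round-trip screening factor e^(−2z/δ′_eff(f)) of the covering medium (an
optional peel layer multiplies its own screening factor). Patterns are then
synthesised and corrupted with configurable noise. Defaults: 256×512 pixels
at 0.2 mm/pixel (≈5×10 cm footprint), additive Gaussian noise at 0.5% of
full scale, 8-bit quantization; illumination amplitudes 0.5 (DC) and 0.45
(AC) of full scale so even a 99% reference stays below saturation at every
phase. The AC field is clipped to the DC field where the per-channel
screening surrogate would cross on strongly absorbing structures — a
modulation amplitude cannot physically exceed the mean.

Scene kinds: homogeneous slab; five ink-filled cylinders (absorption ×50,
standing in for strongly absorbing diluted ink) buried at 1, 11, 6, 4 and
2 mm under a nylon-like scatterer (its bulk properties, μ_a = 0.01,
μ_s′ = 1.5 mm⁻¹, are declared placeholders — the real phantom's values are
not known); a bar target (white 0.90 / black 0.05, 2 mm period) under an
attenuating slice; and a disc-shaped bruise (μ_s′ × 0.7 by default — bruise
direction is configurable and recorded in the ground truth) under a
covering slab. Thickness sweeps use the packaged protocol lists (published
thickness ranges such as 1.0–1.1 mm are represented by midpoints) and give
each thickness an independent recorded sub-seed.

**What the generator does not emulate:** heterogeneous radiative transport
(the screening factor is a first-order surrogate, so absolute contrast
levels of buried structures are approximate even though their ordering in
depth and frequency is right), optical blur/PSF, projector distortion,
height-dependent illumination, or speckle. Passing the scene-based tests
therefore demonstrates the correctness of the pipeline's algebra and
decision logic, not instrument-level accuracy on real fruit.

## Statistical choices

Bruise visibility in recovered μ_s′ maps is decided by a one-sided Welch
two-sample test (inside vs outside the disc mask, valid pixels only) at
α = 0.01 — an automatable, conservative stand-in for by-eye recognisability
of the bruise in the mapping. Visibility verdicts are monotone in cover
thickness on the synthetic scenes: detected up to a cutoff, then not.

## Problem sizes

Defaults are full scale (10⁶ photons per Monte Carlo run; 256×512 scenes).
The test suite runs scaled-down sizes chosen so every statistical assertion
sits far inside its tolerance: 1–2×10⁵ photons per transport run (quantile
estimates at these counts differ from the 10⁶-photon values by well under
1%), 24×48 to 64×64 pixel scenes, and 20 random property pairs for the
inversion-recovery study. The acceptance script (`scripts/acceptance.py`)
runs the full 10⁶-photon simulation per wavelength.

## Known limitations

* The screening-factor scene model is not a transport solution; only
  orderings and round-trip identities on uniform regions are quantitative.
* The diffusion forward model degrades for low albedo (μ_s′/μ_a ≲ 20) and
  high frequency; the LUT grid extends beyond the regime where the
  inversion is physically trustworthy, and the residual/validity mask is
  the guard.
* Sampling-depth quantiles at frequencies with R(f) ≤ 5% of R(0) are
  refused rather than extrapolated.
* Two-layer Monte Carlo assumes index-matched layers (one external
  boundary); peel optical properties must be user-supplied.
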