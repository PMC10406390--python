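# Methods

This note documents the models, conventions and numerical choices behind
`mmoblique`, and what the synthetic phantom does and does not emulate.

## The measurement model

A backscattering Mueller-matrix polarimeter in the dual-rotating-retarder
(DRR) scheme consists of a fixed horizontal polarizer P1 and a rotating
quarter-wave plate R1 on the illumination side, and a rotating quarter-wave
plate R2 followed by a fixed horizontal polarizer P2 on the detection side.
R1 and R2 advance at a fixed 1:5 rate ratio while `n_frames = 30` intensity
images are recorded. With Mueller calculus the frame-k intensity at a pixel
is a linear functional of the sample's Mueller matrix M:

    I_k = aᵀ(r2_k) · M · s(r1_k),   s = R(δ, r1) P(0) [1,0,0,0]ᵀ,
                                    aᵀ = row 0 of P(0) R(δ, r2),

so stacking the 30 rows w_k = a ⊗ s gives a 30×16 measurement matrix W and
per-pixel reconstruction is the least-squares solve M̂ = W⁺ I. On noiseless
rendered frames this round-trips to better than 1e-10 for arbitrary M.

**Choices.**

* R1 step Δ = 6°/frame: 30 frames span 180° of R1 (so the doubled-rate
  phase x = 2·r1 spans a full 360° cycle) and 900° of R2. The scheme fixes
  30 frames and the 1:5 ratio but not Δ; 6° is the standard choice and the
  resulting W has full column rank at δ = 90° (verified numerically; rank
  collapses to ≤ 4 at δ = 0, and `render_frames`/`reconstruct_mm` refuse
  rank-deficient designs with a hint to change Δ).
* Inversion by pseudoinverse rather than the classical closed-form
  Fourier-coefficient decoding. Both are exact on noiseless data; the
  pseudoinverse needs no case analysis and its noise amplification is
  transparent (the per-element noise gain is the row norm of W⁺; the worst
  off-diagonal gain of the default design is 5.84 per unit frame noise).
  The truncated Fourier fit I = α0 + Σₙ(αₙ cos nx + βₙ sin nx), n ≤ 12,
  x = 2·r1, is retained as a diagnostic surface
  (`fit_fourier_coefficients`); 12 is exactly the highest frequency the
  quarter-wave-product signal contains.
* Retardance δ is configurable (nominal 90°) for retarder-error studies;
  no polarization-component calibration terms are modeled. The hardware
  criterion "system error within 1%" is represented in tests by frame
  noise calibrated through the 5.84 noise gain (σ = 4e-4 of the frame
  intensity keeps all off-diagonal element errors ≤ 0.01).
* M11 normalization masks pixels with |M11| < 1e-6 × max|M11| as NaN;
  masked pixels are excluded from every downstream statistic.

## The phantom and its distortion model

The synthetic sample is a concentric-fiber disk imaged end-on: each pixel's
value depends only on its azimuth φ about the ring center (measured
counterclockwise from the +x image axis; for a concentric phantom the fiber
orientation at a pixel is the ring tangent, i.e. the same coordinate up to
a fixed 90° offset, which is absorbed into the per-element phases). The
M11-normalized elements fall into three azimuthal families, each
B + A·cos(p(φ − φ₀)) at normal incidence:

| family | elements | p | default A, B, φ₀ |
|---|---|---|---|
| non-periodic | M11, M44 | 0 | — , 1.0 / 0.55 , — |
| two-periodic | M12, M21, M13, M31 | 2 | 0.25, 0, 0° (45° for M13/M31) |
| four-periodic | M22, M33, M23, M32 | 4 | 0.30, 0.30 (0 for M23/M32), 0° (22.5°) |
| weak | M14, M41, M24, M42, M34, M43 | 0 | 0, 0.02, — |

The reference study plots these curves but never tabulates amplitudes, so
the defaults are package choices: large enough to resolve the periodic
structure cleanly, small enough that every normalized element stays within
[−1, 1] under all distortions. The weak elements (circular
retardance/diattenuation block) are near-zero constants, reflecting their
insensitivity in backscattering from fibrous media.

Oblique incidence at angle θ distorts the curves through six knobs, each a
smooth function of θ (`DistortionProfile`); the functional forms are this
package's phenomenological model — the physical study shows only their
effects, so monotone testability drove the design:

* **baseline shift** b(θ) = 0.15·sin θ — subtracted from M44 and the
  four-periodic baselines, added/subtracted antisymmetrically to the
  M12/M21 and M13/M31 baselines (the transpose pairs drift apart in
  opposite directions).
* **symmetry breaking** s(θ) = 0.6·sin θ — scales the amplitudes of
  M12/M13 by (1+s) and of M21/M31 by (1−s), so the pair difference
  |M12 − M21| grows monotonically with θ.
* **collapse depth** c(θ) = min(1, 1.05·sin θ) — period degeneracy, below.
* **phase retardance** ψ(θ) = 20°·sin θ — a common phase added to all
  periodic elements.
* **transposition** — logistic gate 1/(1 + exp(−(θ − 60°)/2.5°)); above
  the threshold each off-diagonal element mixes toward its transpose
  partner's curve, emulating the value swap seen only at prominent
  incidence (beyond ~50°).
* **diagonal modulation** d(θ) = 0.15·sin θ — a two-periodic modulation of
  M44 (and of the raw M11 pattern in unnormalized output) peaking at
  90°/270°, the vertical-fiber signal enhancement.

**Period degeneracy.** Collapse depth c ∈ [0, 1] blends the four-periodic
cosine toward an element-specific degenerate waveform with two cycles per
turn:

    shape(φ; c) = (1 − c) · cos(4(φ − φ₀)) + min(c/0.05, 1) · target(φ; c)

* M33 (*square mode*): target = sign(u)·|u|^(1−c) with u = cos(2(φ − 45°)).
  At c = 1 this is an ideal square wave (transitions at ±45°); for
  intermediate c the surviving four-periodic ripple puts twin peaks at
  45° ± x*(c) with x* shrinking monotonically (the balance point satisfies
  cos(2x*)^(2−a) = a·bw/(4(1−c)), a = 1−c), so the P−P gap decreases while
  the odd-harmonic ratios approach 4A/(nπ) and Cs falls toward 0 — the two
  degeneracy signatures move together, as in the physical measurements.
* M22 (*impulse mode*): target = mean-centered |sin φ|^(2m), m = 1 + 5c —
  a sharpening impulse train peaked at 90°/270°, so the peaks at 0°/180°
  collapse and the curve kurtosis rises with θ.
* M23/M32 (*generic mode*): target = cos(2(φ − φ₀)).

A plain multiplicative attenuation window at the collapse azimuths was
tried first and rejected: no parameterization of it reproduces all three
required phenomena at once (monotone Cs decrease, monotone twin-peak
convergence, and a square-wave limit), because the window either preserves
the 90° period (no two-cycle content) or pins the twin peaks at the window
edges. The blend above was verified numerically over the whole sweep
before the test values were frozen.

The cap 1.05·sin θ (c ≈ 0.80 at θ = 50°) keeps the residual ripple — the
twin peaks themselves — above the 5% prominence floor of the peak detector
across the 5–50° study range; full collapse (c = 1) remains reachable by
setting the knob directly.

**Noise and determinism.** Additive zero-mean Gaussian noise of
configurable σ (default 0 in the API; pipeline examples use 0.002,
consistent with a percent-level calibrated system) is applied to every
channel using `numpy.random.default_rng(seed)`; identical parameters and
seed reproduce images bit-identically.

## Ring sampling

Azimuthal curves are sampled at 360 positions (1° resolution) on a ring of
radius 200 px (default; smaller phantoms use proportionally smaller rings)
with 11 radial sub-samples bilinearly interpolated across ±5 px and
averaged; masked sub-samples are dropped, and a fully masked ray yields
NaN. The reference procedure names a 200 px ring and "interpolation"
without specifying the kernel or resolution; bilinear at 1° is the
documented choice. The painted annulus of the synthetic phantom is wider
(±12 px) than the analysis ring so that interpolation never straddles the
fiber/background boundary; with this margin extraction matches the
generator ground truth to ~2e-5, well inside the 1e-3 interpolation
tolerance used in tests.

## Statistics

* **Kurtosis** is the exact population (biased, non-excess) form m4/m2² —
  the normal-distribution reference value is 3, a sinusoid gives 1.5, and
  any non-constant sample gives ≥ 1. No sample-size correction is applied.
  Constant curves raise a distinct error instead of returning NaN; the
  pipeline records NaN with a warning for such channels (the noiseless
  normalized M11 is the standard case).
* **Peak detection** runs on a circularly smoothed copy (moving average,
  window 5 samples) with prominence ≥ 5% of the curve range, circular
  boundary handling (the curve is tiled), and parabolic sub-sample
  refinement of extremum locations; reported heights are raw values at the
  detected samples. P−P is the height difference of consecutive peaks
  within a half-turn; P−V the peak-to-following-valley difference.
* **Twin-peak gap**: circular peak separations in a twin-peak structure
  alternate between the intra-pair gap and the pair spacing; the mean of
  the smaller half of the separations (accepted when below one nominal
  period, 90°) is the gap, normalized by the two-period span 180°. This
  rule is invariant to global phase shifts of the curve, which a
  fixed-window pairing is not; it returns NaN for curves with no twin
  structure (e.g. a pure four-period cosine, whose separations are all
  exactly 90°).
* **FDH**: 256 bins over [−1, 1] by default; values outside the range are
  clipped into the boundary bins so counts always conserve the unmasked
  pixel count.

## Harmonic analysis and Cs

Spectra use the DFT of the uniformly sampled 0–360° curve with the 2/N
amplitude convention (unit cosine → Aₙ = 1), harmonic index n in cycles
per 360°. Parseval consistency and equivalence with a brute-force O(N²)
DFT summation are tested. For an N = 360 sampled square wave the discrete
amplitudes are 4A/(N·sin(πn/N)), within 0.07% of 4A/(nπ) for n ≤ 7, so
the 1% analytic check is comfortably met.

`square_wave_coefficient` evaluates Cs from four explicit amplitudes. For
spectra, `cs_from_spectrum` takes an index map naming which bins play the
1st/3rd/5th/7th roles; the default {1:2, 3:6, 5:10, 7:14} treats the half
turn — the fundamental of a degenerated four-periodic curve — as the base
period. The reference table's own indexing convention for M33 cannot be
reconciled with a naive 360°-window DFT (its dominant "1st" harmonic would
be the 4th bin); the explicit map keeps the computation
convention-independent, and the published Cs column is reproduced exactly
from the printed amplitudes regardless.

Periodicity classification: a curve is *non-periodic* when no harmonic
amplitude reaches 0.02 or the dominant harmonic carries < 30% of the
baseline-removed energy; otherwise the dominant index labels it
*two-periodic* (n = 2) or *four-periodic* (n = 4), and any disagreement
with the element's expected undistorted family is reported as *degenerate*.

## What the phantom does and does not show

The generator reproduces the *structure* of the oblique-incidence
phenomenology — the element taxonomy, the monotone degeneracy and
symmetry-breaking trends, the square-wave limit — under controlled,
seedable conditions, which is what the pipeline's correctness tests need.
It does not model the physics that produces those effects: no cylinder
scattering, no speckle or camera noise model, no polarization aberrations,
and its default amplitudes are not measurements of any physical phantom.
Consequently, quantitative values tied to a physical sample (e.g. a
particular kurtosis excursion, or the absolute harmonic amplitudes of a
real silk phantom) are outside what passing tests demonstrate; trend and
limit properties are the meaningful claims. Problem sizes in the tests
(240 px images, ring radius 100, seven-angle sweeps) are chosen to keep
the full suite in a few seconds while leaving every geometric ratio —
ring radius to width, samples per period — at the defaults' proportions.

## Degenerate inputs and edge cases

* Rank-deficient acquisition designs (δ = 0, pathological Δ) are rejected
  with actionable errors; negative input intensities log a warning and
  proceed (least squares is well defined).
* Fully masked azimuth rays, empty ROIs, constant curves, and curves with
  no prominent extrema each produce a defined result or a distinct error —
  never a silent NaN.
* `n_samples ≥ 8`, `n_frames ≥ 16`, `n_max < N/2`, and annulus-inside-image
  preconditions are enforced with named errors.
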