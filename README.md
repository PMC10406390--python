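# mmoblique

Quantitative analysis of how **oblique incidence** distorts **backscattering
Mueller-matrix (MM) polarimetry** of fibrous samples.

Non-collinear backscattering polarimeters illuminate the sample at an angle
θ between the illumination (PSG) and detection (PSA) arms to reject surface
glare — and in endoscopic imaging uneven tissue surfaces impose a range of
relative incidence angles whether we like it or not. Tilting the geometry
distorts the measured MM in element-specific ways, producing false-positive
diattenuation and false-negative anisotropy if ignored. This package gives
the full simulation-and-analysis chain needed to characterize those
artifacts:

* **Phantom synthesis** — 16-channel MM images of a concentric-fiber
  phantom whose M11-normalized elements follow the canonical azimuthal
  families (constant diagonals; two-periodic off-diagonal block M12, M21,
  M13, M31; four-periodic central block M22, M33, M23, M32), with
  parameterized θ-dependent distortions: baseline shift, symmetry breaking
  between transpose pairs, period-degeneracy collapse, phase retardance,
  element transposition, and azimuthal modulation of the diagonals.
* **DRR acquisition model** — forward-renders the 30-frame
  dual-rotating-retarder acquisition (quarter-wave plates rotating at a
  1:5 rate ratio between fixed horizontal polarizers) from any MM image
  via Mueller calculus, and inverts it per pixel by pseudoinverse of the
  30×16 measurement matrix; the truncated Fourier series of the intensity
  signal (n ≤ 12) is available as a diagnostic.
* **Ring sampling** — azimuthal dependent curves of each element along a
  ring (default radius 200 px), bilinearly interpolated and averaged over
  the ring width.
* **Curve statistics** — mean μ = (1/n)Σpᵢ and population kurtosis
  k = (1/n)Σ(pᵢ−μ)⁴ / ((1/n)Σ(pᵢ−μ)²)², peak/valley metrics (P−P, P−V,
  twin-peak P−P gap), and frequency distribution histograms (FDHs).
* **Harmonic analysis** — FFT amplitudes Aₙ (2/N normalization, so a unit
  cosine gives Aₙ = 1), and the **square-wave coefficient**

      Cs = |3·A3 − A1| + |5·A5 − A1| + |7·A7 − A1|,

  which vanishes exactly when the odd-harmonic amplitudes satisfy the
  ideal square-wave ratios A1 = 3A3 = 5A5 = 7A7 (a square wave of
  amplitude A has Aₙ = 4A/(nπ) for odd n). Cs quantifies the collapse of
  four-periodic curves toward two-period square-wave-like shapes as θ
  grows — the period-degeneracy signature.

## Worked example

```python
import numpy as np
from mmoblique import (
    PhantomParams, generate_phantom_mm, extract_azimuthal_curve,
    harmonic_amplitudes, cs_from_spectrum, find_peaks_valleys,
)

for theta in (5.0, 20.0, 50.0):
    params = PhantomParams(image_size=(240, 240), ring_radius=100,
                           incidence_theta=theta)
    mm = generate_phantom_mm(params)
    curve = extract_azimuthal_curve(mm, (3, 3), radius=100, half_width=5)
    spectrum = harmonic_amplitudes(curve)
    peaks = find_peaks_valleys(curve)
    print(f"theta={theta:4.0f}  Cs={cs_from_spectrum(spectrum):.3f}  "
          f"P-P gap={peaks.pp_gap:.3f}")
```

prints

```
theta=   5  Cs=0.873  P-P gap=0.409
theta=  20  Cs=0.754  P-P gap=0.382
theta=  50  Cs=0.336  P-P gap=0.345
```

As the incidence angle grows, the M33 curve's square-wave coefficient falls
toward 0 (its odd harmonics approach the ideal square-wave ratios) and the
twin peaks of each period converge (the normalized P−P gap shrinks): the
four-periodic curve is degenerating toward a two-period square wave, which
is exactly the signature that marks unreliable linear anisotropy readings
at large θ.

The same analysis runs from the shell:

```bash
mmoblique simulate --out sim --theta 20 --seed 1
mmoblique analyze --mm sim/phantom_mm.tiff --out analysis
mmoblique sweep --config sweep.yaml --out results/sweep --seed 1
```

`sweep` writes one subdirectory per θ (MM TIFF, curves CSV, spectra CSV,
stats CSV) plus a `summary.csv` table of mean, kurtosis, A1–A8, Cs, P−P,
P−V and P−P gap per element per θ.

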