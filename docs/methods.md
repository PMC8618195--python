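# Methods

## Two-phase Brillouin model

A backscattering Brillouin spectrum of lamellar bone is modelled as two
inelastic peaks over a constant background on the Stokes side: P_SOFT in
4–13 GHz (disordered extracellular matrix, osteocytes, marrow) and P_HARD
in 13–32 GHz (mineralized collagen bundles). Both peaks coexist in one
2×10 µm scattering volume because the two matrix organizations interleave
at sub-micrometre scale. The analysis is deliberately fit-free:

- **Band moment.** ν̄_b = Σ Iᵢνᵢ / Σ Iᵢ over the channels of band *b*,
  inclusive at both edges. The two default bands share the 13 GHz edge;
  the shared channel is assigned to the soft band (deterministic
  tie-break). An empty band yields NaN, never 0, and NaN propagates into
  the per-pixel feature record so ROI statistics can mask it.
- **Fractions.** Band areas are trapezoidal integrals. The soft area is
  divided by a scattering-efficiency ratio (config `efficiency_ratio`,
  default 1 — the published coefficient for bone was never released) and
  the pair is normalized to 100 %. Normalizing per pixel absorbs the
  rough-surface filling factor, which is why every feature is invariant
  under multiplication of the spectrum by a positive constant.
- **Modulus.** M = ν̄² λ² κ / 4 with λ the laser wavelength (nm) and
  κ = ρ/n² (g/cm³), evaluated with explicit SI conversion and returned in
  GPa. κ defaults to 1.29 g/cm³. The sources are ambiguous about whether
  the printed 1.29 is ρ/n or ρ/n²; the conversion formula divides by n²,
  so the constant is carried as the single combined κ = ρ/n² actually
  used, and it is configurable. At ν = 10 GHz, λ = 532 nm this gives
  9.1275 GPa, matching an independent unit-tracked evaluation to 1e-9.
- **Voigt average.** M_avg = (I_s M_s + I_h M_h)/(I_s + I_h) — the
  upper (iso-strain) bound of composite stiffness, invariant under common
  rescaling of the fractions and bounded by the two phase moduli. A phase
  with zero fraction may carry a missing modulus without poisoning the
  average.

**Background.** An optional constant-background correction (median
intensity outside both bands, subtracted and clipped at zero) is off by
default and enabled via `subtract_background`. It is the recommended
setting whenever spectra carry a flat instrumental background, and all
recovery benchmarks in this repository run with it enabled.

**Known estimator bias.** The band moment of a Lorentzian peak truncated
to a finite band is biased toward the band's far side by
(γ/2π)·ln(((hi−ν₀)²+γ²)/((lo−ν₀)²+γ²))/P, γ = FWHM/2, P the in-band
probability mass — proportional to the linewidth — and the opposite
peak's in-band tail adds a cross-band bias that no constant-background
correction can remove. This is intrinsic to the moment estimator, not an
implementation artifact; on real, broad bone peaks it shifts band centers
by tenths of GHz. It drives the synthetic-generator width defaults below.

## Raman markers

Preprocessing follows standard bone-Raman practice. The fluorescence
baseline is removed with an iterative-clipping polynomial fit: fit a
polynomial (default order 5) to the spectrum, replace every point above
the fit by the fit, repeat to convergence (fit change < 1e-6 of the data
maximum) or an iteration cap, subtract, clip at zero. The axis is mapped
to [−1, 1] before fitting, and because the design matrix is fixed the QR
factorization is computed once per spectrum. The default iteration cap is
200: at 50 iterations the fit is still visibly drifting (the residual
under the weak 965 cm⁻¹ band of lipid-rich pixels is twice its converged
value), while convergence is reached well before 200 on all synthetic
profiles. Peak-dense regions bias any polynomial baseline slightly
upward; with the defaults the residual distortion of marker peaks stays
below ~5 % for bands with FWHM ≤ 20 cm⁻¹.

Spectra are then normalized so the maximum within 1445 ± 10 cm⁻¹ (CH₂
wagging, present in both lipids and collagen) equals exactly 1 — a window
maximum rather than a single channel, so instruments with different axis
grids behave identically. Markers:

- **mineral-to-matrix** = window-maximum intensity at 965 ± 8 cm⁻¹
  (ν₁PO₄³⁻) over 860 ± 8 cm⁻¹ (proline). Window maxima match the
  intensity-ratio convention and are robust to small calibration shifts;
  the ratio is scale-invariant, so it does not matter that it is computed
  after normalization.
- **CH moment** = band moment over 2800–3100 cm⁻¹. Pure-lipid spectra sit
  near 2872 cm⁻¹ (CH₂), pure-protein near 2935 cm⁻¹ (CH₃); the moment is
  strictly monotone in the lipid:protein amplitude ratio between those
  limits.
- **heme–amide moment** = band moment over 1500–1720 cm⁻¹; hemoglobin at
  1580 cm⁻¹ pulls it below the amide-I/fatty-acid value near 1660 cm⁻¹,
  flagging red-marrow territory.

An optional hydroxyapatite-crystallinity estimate (FWHM of the 965 cm⁻¹
band by interpolated half-maximum crossings) is provided but excluded
from the default feature set, since the reference protocol did not use it.

## PCA classification

Preprocessed spectra cropped to the 800–1780 cm⁻¹ fingerprint window
(limits inclusive) form an observation × wavenumber matrix; pixels whose
normalization fails are dropped and logged. The decomposition is a plain
SVD of the column-mean-centered matrix — mean centering only, no
autoscaling, matching the default of the standard PCA routine the
protocol was built on (autoscaling is available via the matrix API).
Loadings are orthonormal; each component's sign is fixed so its
largest-magnitude weight is positive, making results reproducible across
platforms. Explained variance is reported as a percentage of the total
column variance, so retaining every component sums to 100.

Group separation along a component is the one-vs-rest standardized mean
separation |mean_g − mean_rest| / pooled within-group SD; a component
"divides" a group when this exceeds a threshold (default 2). Because the
sign convention is algebraic, directional claims ("the lipid channels
load toward the lipid-rich group") are evaluated after orienting the
loading toward the group of interest by the sign of its mean-score
offset.

## Synthetic phantoms

The generator emulates the statistical structure the analysis assumes,
with full per-pixel ground truth; it is the package's only data source.

- **Brillouin spectra**: two Lorentzians on a 2–35 GHz axis (0.05 GHz
  step, Stokes side only), areas proportional to the configured volume
  fractions, constant background at 1 % of the peak maximum. Default
  linewidths are FWHM 0.15 GHz for both peaks — deliberately idealized so
  that the moment estimator's truncation and cross-band biases (see
  above, ∝ linewidth; ≈ 0.04 GHz worst-case over the cortical parameter
  ranges) stay below the generator's recovery guarantees (±0.05 GHz on
  band centers, ±1 point on fractions, 2 % on moduli). Realistic bone
  linewidths are broader and can be configured, at the documented cost of
  estimator bias; passing recovery tests therefore certifies the
  pipeline's bookkeeping, not the moment estimator's accuracy on broad
  real-world peaks.
- **Raman spectra**: five component templates over 250–3700 cm⁻¹ at
  1 cm⁻¹ — mineral (965, 1030, 1068), collagen/protein (860, 870, 1003,
  1242, 1445, 1660, 2935), lipid (1298, 1445, 1745, 2872), heme (1170,
  1580), carotenoid (~1140) — as Lorentzian bands (FWHM 10–28 cm⁻¹)
  scaled by non-negative composition weights, on a smooth decaying
  polynomial fluorescence baseline (default amplitude half the tallest
  peak). Because bands overlap, marker ground truth is defined as the
  markers of the ideal noise- and baseline-free template spectrum
  (`raman_template_truth`), not closed-form band parameters.
- **Noise**: Poisson counts scaled so the peak SNR equals the configured
  level (√N at the apex); 0 means noiseless; the per-pixel features are
  scale-invariant, so the absolute count level is immaterial. Default
  SNR 50, typical of photon-counting acquisitions at ~1 s × 55
  accumulations.
- **Phantoms**: cortical maps embed two elliptical, lipid-rich,
  high-soft-fraction vessel channels in a mineral-rich lamellar matrix;
  trabecular maps alternate hard spicule bands with marrow bands randomly
  labelled yellow (lipid-rich) or red (heme-rich, lowest soft-phase
  frequency). Per-pixel parameters are drawn from per-region ranges with
  a mandatory seed; two runs with one seed are byte-identical.
- **Study fixture**: six homogeneous ROI datasets spanning treatment
  (frozen vs PFA-fixed/ethanol-stored) and anatomy (diaphysis vs
  epiphysis). Region means are chosen to be arithmetically consistent
  with the published per-ROI mean moduli: fixation multiplies the
  soft-phase frequency by √1.34 (cortical) and √1.37 (trabecular),
  depletes the soft volume fraction by ~70 % and ~60 %, and strips lipid
  and heme weight; the epiphyseal trabecular marrow is heme-enriched
  (red) versus the lipid-dominated diaphyseal medullary canal, and the
  epiphyseal cortical plate is slightly more mineralized and less
  heterogeneous than the diaphyseal ring.

What the phantoms do **not** emulate: anti-Stokes/quasi-elastic channels,
elastic anisotropy and phonon attenuation, instrument response functions,
cosmic rays, spatial correlation beyond region membership, and the real
linewidths discussed above. Passing tests on phantoms demonstrates the
estimators recover their own generative parameters under the stated
conditions — not that those conditions exhaust real bone spectra.

## ROI statistics and comparisons

ROIs are axis-aligned pixel-index rectangles (lo-inclusive, hi-exclusive).
Per feature the unmasked pixels yield n, mean, sample SD (n−1), SEM =
SD/√n, quartiles and a 30-bin histogram over the observed range. The "±"
uncertainties quoted alongside ROI means are SEMs; with thousands of
pixels per ROI this matches the magnitude of published per-ROI
uncertainties, and it is documented here as an assumption. Percent
changes between ROI means are reported signed, with a companion value
rounded to the nearest integer percent for comparison against "about
N %" statements.

## Problem sizes and numerical choices

The validation suite uses a 32×32 noiseless cortical phantom for
per-pixel recovery, 100 seeded pixels at SNR 50 for fraction recovery,
6×6-pixel ROIs for the study fixture, and 1000 random spectra for the
moment oracle — sizes at which every check runs in seconds to a couple of
minutes on one CPU while the statistics are already stable. Degenerate
inputs are defined throughout: empty bands → NaN (flagged, masked,
omitted from statistics with a warning when an ROI has none left); both
band areas zero → missing fractions; zero reference intensity → the
pixel's Raman features are flagged and the pixel is dropped from the PCA
matrix; rank-deficient PCA requests return the available components with
a warning; percent change against a zero reference raises. Text output
uses 6 significant digits, below every tolerance above.
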