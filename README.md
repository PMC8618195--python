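# brams

Chemo-mechanical analysis of paired Brillouin–Raman micro-spectroscopy
(BRmS) maps of bone tissue.

BRmS scans a tissue section on a regular x–y grid (typically 3 µm steps)
and records, at every pixel, a Brillouin spectrum (GHz frequency shifts of
light scattered by thermally excited acoustic waves — mechanics) and a
Raman spectrum (cm⁻¹ vibrational shifts — chemistry). In lamellar bone the
Brillouin spectrum shows **two** peaks from the same scattering volume: a
soft one (4–13 GHz) from the disordered extracellular matrix and marrow
constituents, and a hard one (13–32 GHz) from mineralized collagen
bundles. This package turns such maps into quantitative per-pixel features
and ROI-level comparisons, for spectroscopists and bone-biomechanics
researchers who want the analysis without the instrument control.

## The analysis

Per pixel, for each band *b* ∈ {soft, hard}:

- **band moment** ν̄_b = Σᵢ Iᵢνᵢ / Σᵢ Iᵢ over the band's channels — a
  fit-free band-center estimator robust to heterogeneous lineshapes;
- **longitudinal elastic modulus** M_b = ν̄_b² λ² (ρ/n²) / 4 in
  backscattering, with λ = 532 nm and ρ/n² = 1.29 g/cm³ treated as
  constant across the tissue;
- **volume fractions** I_soft + I_hard = 100 %, from efficiency-weighted
  integrated band intensities normalized per pixel (the normalization
  cancels the rough-surface filling factor);
- **Voigt average** M_avg = (I_soft·M_soft + I_hard·M_hard) / (I_soft + I_hard),
  the composition-weighted tissue modulus.

The paired Raman spectrum is baseline-corrected (iterative-clipping
polynomial fit), normalized to the CH₂ wagging band at 1445 cm⁻¹, and
reduced to three markers: the mineral-to-matrix ratio I(965)/I(860)
(ν₁PO₄³⁻ over proline — collagen mineralization), the CH₂-CH₃ band moment
(2800–3100 cm⁻¹ — lipid-to-protein balance), and the heme–amide band
moment (1500–1720 cm⁻¹ — red-marrow content). Feature maps, rectangular
ROI statistics (mean, SD, SEM, quartiles, histograms), percent-change
comparisons between ROIs, and a deterministic PCA of the 800–1780 cm⁻¹
fingerprint region complete the pipeline. A synthetic tissue-phantom
generator (cortical and trabecular, with full per-pixel ground truth)
makes every stage testable; no measured data ships with the package.

## Worked example

```sh
python examples/01_single_spectrum_mechanics.py
```

```
truth:      nu_soft 6.86 GHz, nu_hard 18.64 GHz, I_soft 34.0 %
recovered:  nu_soft 6.99 GHz, nu_hard 18.94 GHz, I_soft 33.6 %
moduli:     M_soft 4.45 GPa, M_hard 32.76 GPa
Voigt average M = 23.23 GPa
```

One simulated pixel at photon-counting SNR 50: the soft phase (6.86 GHz ≈
4.4 GPa) and the mineralized phase (18.64 GHz ≈ 32 GPa) are recovered from
the same spectrum, and the Voigt average says the pixel as a whole behaves
like a ~23 GPa composite dominated by its two-thirds mineral fraction.

`examples/04_fixation_study_and_pca.py` runs the full study design on the
six-ROI synthetic fixture and prints, among others:

```
fixation, cortical M_avg              +49.4 %
fixation, trabecular M_avg            +71.3 %
epiphysis vs diaphysis, cortical      +17.4 %
epiphysis vs diaphysis, trabecular    -12.0 %
```

PFA fixation with ethanol storage strips lipids and depletes the soft
fraction, stiffening the apparent tissue average in both tissue types;
the epiphyseal cortical plate is stiffer than the diaphyseal ring while
the epiphyseal trabecular region (red, heme-rich marrow) is softer. The
script's PCA section shows the first principal component isolating the
frozen trabecular ROI through its lipid-band loadings.

The other examples cover Raman markers by tissue composition
(`02_raman_markers.py`) and phantom ROI statistics
(`03_phantom_roi_comparison.py`). A thin CLI mirrors the stages:
`brams simulate | extract | map | compare | pca` (see `brams --help`).

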