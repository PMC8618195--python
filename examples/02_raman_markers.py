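"""Chemical markers from a Raman bone spectrum.

Builds two synthetic tissue compositions (mineralized cortical matrix vs
lipid-rich marrow), runs the preprocessing pipeline (fluorescence-baseline
removal, normalization to the 1445 cm-1 CH2 band) and prints the three
markers: mineral-to-matrix ratio, CH2-CH3 band moment and heme-amide band
moment.
"""

from brams import (AnalysisConfig, PixelTruth, extract_raman_features,
                   simulate_raman_spectrum)

config = AnalysisConfig(subtract_background=True)

compositions = {
    "cortical matrix": {"mineral": 1.0, "collagen": 1.0, "lipid": 0.15},
    "yellow marrow": {"mineral": 0.1, "collagen": 0.7, "lipid": 1.2},
    "red marrow": {"mineral": 0.1, "collagen": 0.8, "lipid": 0.4,
                   "heme": 0.8},
}

print(f"{'tissue':16s} {'mineral/matrix':>14s} {'CH moment':>10s} "
      f"{'heme moment':>12s}")
for name, comp in compositions.items():
    truth = PixelTruth(nu_soft=6.6, nu_hard=18.0, frac_soft=50.0,
                       raman_composition=comp, noise=50.0)
    spectrum = simulate_raman_spectrum(truth, seed=7)
    f = extract_raman_features(spectrum, config)
    print(f"{name:16s} {f.mineral_to_matrix:14.2f} {f.ch_moment:10.1f} "
          f"{f.heme_moment:12.1f}")

print()
print("High mineral-to-matrix marks mineralized collagen; a CH moment near")
print("2872 cm-1 marks lipids (marrow fat) against the 2935 cm-1 protein")
print("stretch; a low heme-amide moment (toward 1580 cm-1) marks hemoglobin,")
print("i.e. red rather than yellow marrow.")
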