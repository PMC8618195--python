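"""Treatment/anatomy study on the six-ROI fixture, with fingerprint PCA.

Reproduces the analysis design used to contrast preservation treatments
(frozen vs PFA-fixed + ethanol-stored) and anatomical regions (diaphysis
vs epiphysis): per-ROI mean moduli, percent changes between ROIs, and a
PCA of the fingerprint-region Raman spectra that classifies the ROIs.
"""

import numpy as np
import pandas as pd

from brams import (AnalysisConfig, ROI, SpectralMatrix, build_matrix,
                   generate_study_fixture, group_separation, map_features,
                   percent_change, roi_statistics, run_pca)

config = AnalysisConfig(subtract_background=True)
shape = (6, 6)
datasets = generate_study_fixture(seed=11, shape=shape, noise=50.0,
                                  config=config)

summaries = {}
for name, (smap, _) in datasets.items():
    fmap = map_features(smap, config)
    summaries[name] = roi_statistics(fmap, ROI(name, 0, 6, 0, 6))
    s = summaries[name]
    print(f"{name:30s} M_avg {s.mean('M_avg'):5.2f} +/- {s.sem('M_avg'):.2f} "
          f"GPa   I_soft {s.mean('I_soft'):5.1f} %")

print()
for label, feat, ref, cmp_ in [
    ("fixation, cortical M_avg", "M_avg",
     "frozen_cortical_diaphysis", "fixed_cortical_diaphysis"),
    ("fixation, trabecular M_avg", "M_avg",
     "frozen_trabecular_diaphysis", "fixed_trabecular_diaphysis"),
    ("epiphysis vs diaphysis, cortical", "M_avg",
     "frozen_cortical_diaphysis", "frozen_cortical_epiphysis"),
    ("epiphysis vs diaphysis, trabecular", "M_avg",
     "frozen_trabecular_diaphysis", "frozen_trabecular_epiphysis"),
]:
    p = percent_change(summaries[ref].mean(feat), summaries[cmp_].mean(feat))
    print(f"{label:36s} {p:+6.1f} %")

# PCA over the four diaphyseal treatment ROIs
four = ["frozen_cortical_diaphysis", "fixed_cortical_diaphysis",
        "frozen_trabecular_diaphysis", "fixed_trabecular_diaphysis"]
mats = [build_matrix(datasets[k][0], rois=[ROI(k, 0, 6, 0, 6)], config=config)
        for k in four]
matrix = SpectralMatrix(
    np.vstack([m.data for m in mats]), mats[0].wavenumbers,
    pd.MultiIndex.from_tuples([t for m in mats for t in m.labels],
                              names=["roi", "x", "y"]))
result = run_pca(matrix, 3)
print()
print("explained variance (%):", np.round(result.explained_variance_pct, 1))
sep = group_separation(result)
pc1 = sep[sep.component == 1].sort_values("separation", ascending=False)
print(pc1[["group", "separation", "divides"]].to_string(index=False))
print()
print("PC1 isolates the frozen trabecular ROI: its marrow keeps the lipid")
print("signature that fixation + ethanol storage strips away; fixation also")
print("raises every averaged modulus, while the epiphyseal trabecular ROI")
print("(red, heme-rich marrow) is softer than the diaphyseal one.")
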