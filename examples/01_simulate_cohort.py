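"""Simulate a cohort of retinal log-reflectance spectra with known ground truth.

Each subject's spectrum is a smooth fundus baseline plus random loadings on
ocular-constituent absorbance curves (media, melanin, haemoglobin), plus —
for cases only — a short-wavelength amyloid signature, plus noise.
"""

import numpy as np

import hsretina as hs

config = hs.SyntheticCohortConfig(n_case=15, n_control=20, seed=42)
matrix, truth = hs.simulate_cohort(config)

print(f"cohort matrix: {matrix.X.shape[0]} subjects x {matrix.X.shape[1]} wavelengths")
print(f"groups: {np.sum(matrix.labels == 'case')} cases, "
      f"{np.sum(matrix.labels == 'control')} controls")
print(f"planted signal amplitude: {truth.signal_amplitude:.4f} log-reflectance units")

# nuisance loadings dwarf the group signal, which is why the discriminant
# must remove within-class axes before scoring
dominant = max(config.nuisance_sds.values())
print(f"dominant nuisance SD {dominant:.2f} vs signal amplitude "
      f"{truth.signal_amplitude:.2f}: ocular variability, not amyloid, "
      "dominates the spectra")
raw_auc = hs.roc_auc(matrix.X @ truth.signature, matrix.labels).auc
print(f"AUC of naive scoring along the signature without correction: {raw_auc:.2f}")
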