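"""Phospholipid-to-protein ratio of adhesive-pad material from FTIR.

Builds a synthetic pad spectrum with an ester-carbonyl band (lipids,
~1750 cm^-1) of height 9.79 and an amide I band (protein, ~1650 cm^-1) of
height 3.28, then applies the band-ratio calibration
(I1/I2 - 0.0175)/0.2590.
"""

import numpy as np

import sporecyte as sc

wn = np.arange(1500.0, 1900.0, 0.5)
absorbance = 9.79 * np.maximum(0.0, 1 - np.abs(wn - 1755.0) / 20.0)
absorbance += 3.28 * np.maximum(0.0, 1 - np.abs(wn - 1660.0) / 20.0)
spectrum = sc.FtirSpectrum(wn, absorbance)

i1 = sc.band_intensity(spectrum, *sc.LIPID_BAND_CM1)
i2 = sc.band_intensity(spectrum, *sc.PROTEIN_BAND_CM1)
ratio = sc.lipid_protein_ratio(i1, i2)

print(f"I1 (ester carbonyl, 1730-1800 cm^-1) = {i1:.2f}")
print(f"I2 (amide I,       1650-1700 cm^-1) = {i2:.2f}")
print(f"phospholipid/protein ratio = {ratio:.4g} mol per kg protein")
print("\nA ratio of ~11.5 mol/kg means the pad matrix is a lipid-rich")
print("glycoprotein adhesive rather than pure protein.")
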