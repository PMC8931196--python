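# Absorption spectra used for spectral mixing, expressed in cm^-1 per unit
# relative concentration (volume-fraction-like units, so typical tissue
# concentrations are O(1)).
# Sources: hbo2/hbr computed as whole-blood absorption at 150 g Hb/L from the
# Prahl/Oregon Medical Laser Center tabulated molar extinction coefficients
# (mu_a = ln(10) * eps_molar * 2.33e-3 M); water from Hale & Querry (1973);
# collagen representative of published dry-collagen NIR absorption
# measurements (short-wavelength shoulder at 760 nm, local minimum near
# 840 nm, rise toward the ~910 nm feature).
chromophore,wavelength_nm,epsilon
hbo2,760,3.14
hbo2,840,5.48
hbo2,910,6.54
hbr,760,8.31
hbr,840,3.71
hbr,910,4.18
water,760,0.0266
water,840,0.0362
water,910,0.0780
collagen,760,0.45
collagen,840,0.22
collagen,910,0.50
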