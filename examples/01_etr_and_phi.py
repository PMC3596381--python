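"""From raw fluorescence yields to the electron requirement for carbon fixation.

Builds one FRRf acquisition, derives the quantum-efficiency ratios, computes
the PSII electron transport rate (ETR), and divides by a chlorophyll-
normalised carbon uptake rate to obtain Phi_e,C.
"""

from phiec import (
    FRRfAcquisition, NPsiiSpec, NPsiiMode,
    derive_yields, etr_light_dark, phi_ec, resolve_npsii, unit_conversion_factor,
)

# A mid-light acquisition: moderate non-photochemical quenching has lowered
# the light-chamber yields relative to the dark pair.
acq = FRRfAcquisition(
    F0=0.30, Fm=1.00,            # dark minimal / maximal yields
    F0p=0.27, Fp=0.58, Fmp=0.88,  # light-chamber yields
    sigma_psii=520.0,             # A^2 quanta^-1 (dark)
    sigma_psii_p=470.0,           # A^2 quanta^-1 (light)
    E=250.0,                      # umol quanta m^-2 s^-1
)

y = derive_yields(acq)
print(f"Fv/Fm      = {y.FvFm:.3f}   (dark maximum quantum efficiency)")
print(f"Fq'/Fm'    = {y.FqpFmp:.3f}   (operating efficiency under light)")
print(f"Fq'/Fv'    = {y.FqpFvp:.3f}   (PSII efficiency factor)")
print(f"kappa      = {unit_conversion_factor():.3e} (unit conversion constant)")

npsii = resolve_npsii(NPsiiSpec(mode=NPsiiMode.CONSTANT_EUKARYOTE))
rec = etr_light_dark(acq, y, npsii=npsii)
print(f"ETR        = {rec.etr:.4e} mol e- (mg chl a)^-1 h^-1")

# Carbon uptake measured on the same sample, chlorophyll-normalised:
P_chla = 2.4e-4  # mol C (mg chl a)^-1 h^-1
phi = phi_ec(rec, P_chla, Ek=180.0)
print(f"Phi_e,C    = {phi.phi_ec:.2f} mol e- (mol C)^-1")
print(f"  in theoretical 4-6 band: {phi.in_theoretical_band}; "
      f"E:Ek = {phi.E_to_Ek:.2f} ({'light-limited' if phi.E_to_Ek < 1 else 'saturated'})")
# A Phi_e,C well above 6 means many PSII electrons are consumed by sinks
# other than carbon fixation (e.g. nitrate reduction, alternative flows).
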