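"""Attenuation and optical depth from an irradiance profile or euphotic depth.

Shows the two routes to the diffuse attenuation coefficient K_d and the
optical-depth normalisation used to compare light history across stations.
"""

import numpy as np

from phiec import IrradianceProfile, kd_from_profile, kd_from_zeu, optical_depth, euphotic, e_to_ek

# Route 1: regression on a measured vertical PAR profile
z = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 35.0])
E = 1400.0 * np.exp(-0.12 * z) * (1 + np.random.default_rng(1).normal(0, 0.01, z.size))
kd, r2 = kd_from_profile(IrradianceProfile(z, E))
print(f"Kd from profile      = {kd:.4f} m^-1  (R^2 = {r2:.4f})")

# Route 2: from a satellite euphotic-depth product (1% light level)
kd_sat = kd_from_zeu(38.0)
print(f"Kd from z_eu = 38 m  = {kd_sat:.4f} m^-1")

# Optical depth says where a sample sits in the light gradient:
for depth in (5.0, 25.0, 60.0):
    zeta = optical_depth(kd, depth)
    print(f"z = {depth:5.1f} m -> zeta = {zeta:5.2f}  euphotic: {euphotic(zeta)}")

# Saturation state relative to the PE-curve parameter Ek:
ratio, limited = e_to_ek(E=90.0, Ek=180.0)
print(f"E:Ek = {ratio:.2f} -> {'light-limited' if limited else 'light-saturated'}")
# zeta < 4.6 marks the euphotic zone (>1% of surface light); E:Ek < 1 marks
# irradiance below the onset of saturation for carbon fixation.
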