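"""Underwater light field context: attenuation, optical depth, saturation.

The diffuse attenuation coefficient K_d (m-1) is either regressed from a
vertical irradiance profile (ln E vs depth) or recovered from the euphotic
depth z_eu via K_d = ln(100)/z_eu, z_eu being the 1% surface-PAR depth.
Optical depth zeta = K_d * z harmonises light history across studies;
zeta < 4.6 (~= ln 100) marks the euphotic zone. The ratio E:E_K classifies
a sample as light-limited (<1) or light-saturated (>=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "LN100",
    "EUPHOTIC_ZETA",
    "IrradianceProfile",
    "OpticalContext",
    "kd_from_profile",
    "kd_from_zeu",
    "optical_depth",
    "euphotic",
    "e_to_ek",
]

LN100 = float(np.log(100.0))
#: categorical euphotic-zone threshold on optical depth (2 s.f. of ln 100)
EUPHOTIC_ZETA = 4.6


@dataclass(frozen=True)
class IrradianceProfile:
    """Vertical PAR profile: strictly increasing depths, positive irradiance."""

    depths: np.ndarray
    irradiances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        e = np.asarray(self.irradiances, dtype=float)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "irradiances", e)
        if d.shape != e.shape or d.ndim != 1:
            raise ValueError("depths and irradiances must be 1-D and equal length")
        if d.size < 3:
            raise ValueError("need at least 3 profile points for regression")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("depths must be >= 0")
        if np.any(e <= 0):
            raise ValueError("irradiances must be > 0")
        if np.any(np.diff(e) > 0):
            warnings.warn("irradiance inversion with depth in profile", stacklevel=3)


@dataclass(frozen=True)
class OpticalContext:
    """Light context of one sample: K_d, optical depth, saturation ratio."""

    Kd: float
    z: float
    zeta: float
    euphotic: bool
    z_eu: Optional[float] = None
    E_to_Ek: Optional[float] = None


def kd_from_profile(profile: IrradianceProfile) -> tuple[float, float]:
    """K_d as minus the OLS slope of ln E(z) on z; returns ``(Kd, r_squared)``.

    The surface point is included in the fit. A non-positive slope-derived
    K_d (non-attenuating profile) is an error.
    """
    res = stats.linregress(profile.depths, np.log(profile.irradiances))
    kd = -res.slope
    if kd <= 0:
        raise ValueError(f"non-positive Kd={kd:.4g}: profile does not attenuate")
    return float(kd), float(res.rvalue**2)


def kd_from_zeu(z_eu: float) -> float:
    """K_d from euphotic depth: ln(100)/z_eu (1% light level definition)."""
    if z_eu <= 0:
        raise ValueError("z_eu must be > 0")
    return LN100 / z_eu


def optical_depth(Kd: float, z: float) -> float:
    """Dimensionless optical depth zeta = K_d * z."""
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    return Kd * z


def euphotic(zeta: float) -> bool:
    """True iff the sample sits above the 1% light level (zeta < 4.6).

    The boundary zeta == 4.6 is classified NOT euphotic (strict
    inequality).
    """
    return zeta < EUPHOTIC_ZETA


def e_to_ek(E: float, Ek: float) -> tuple[float, bool]:
    """Ratio of ambient to saturating irradiance; ``(ratio, light_limited)``.

    light_limited is True iff E:E_K < 1; the boundary ratio 1.0 is
    classified saturated.
    """
    if Ek <= 0:
        raise ValueError("Ek must be > 0")
    if E < 0:
        raise ValueError("E must be >= 0")
    ratio = E / Ek
    return ratio, ratio < 1.0


def optical_context(
    Kd: float, z: float, E: float | None = None, Ek: float | None = None,
    z_eu: float | None = None,
) -> OpticalContext:
    """Bundle K_d, zeta, euphotic flag and (optionally) E:E_K for a sample."""
    zeta = optical_depth(Kd, z)
    ratio = None
    if E is not None and Ek is not None:
        ratio, _ = e_to_ek(E, Ek)
    return OpticalContext(Kd=Kd, z=z, zeta=zeta, euphotic=euphotic(zeta),
                          z_eu=z_eu, E_to_Ek=ratio)
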