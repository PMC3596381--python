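"""Carbon fixation normalisation and the electron requirement Phi_e,C.

Chlorophyll-normalised CO2 uptake (mol C (mg chl a)-1 h-1) is combined
with the PSII electron transport rate into the electron requirement for
carbon fixation::

    Phi_e,C = ETR / P_chla        [mol e- (mol C)-1]

A photosynthesis–irradiance (PE) curve — exponential saturation without
photoinhibition, P(E) = Pmax (1 - exp(-alpha E / Pmax)) — lets carbon
uptake be evaluated at the irradiance of the fluorescence measurement so
that both rates refer to the same light level. The light-saturation
parameter is E_K = Pmax / alpha.

The theoretical minimum electron requirement is 4 e- per O2 evolved times
a photosynthetic quotient of 1–1.5 mol O2 (mol CO2)-1, i.e. a band of
4–6 mol e- (mol C)-1; observed field values span roughly 1–60.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .frrf import ElectronTransportRecord

__all__ = [
    "CARBON_MOLAR_MASS",
    "THEORETICAL_BAND",
    "OBSERVED_ENVELOPE",
    "PECurve",
    "CarbonUptakeRecord",
    "PhiRecord",
    "fit_pe_curve",
    "evaluate_pe",
    "daily_to_hourly",
    "phi_ec",
    "etr_to_carbon",
    "theoretical_phi_band",
]

#: g mol-1, for mg C -> mol C conversions
CARBON_MOLAR_MASS = 12.011
#: theoretical Phi_e,C band: 4 e-/O2 x photosynthetic quotient 1–1.5
THEORETICAL_BAND = (4.0, 6.0)
#: flagging envelope around the observed field range (~1.15–54.2)
OBSERVED_ENVELOPE = (1.0, 60.0)

ELECTRONS_PER_O2 = 4.0


def theoretical_phi_band(pq_range: tuple[float, float] = (1.0, 1.5)) -> tuple[float, float]:
    """Phi_e,C band implied by 4 e- per O2 and a photosynthetic quotient range."""
    lo, hi = pq_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid photosynthetic quotient range")
    return ELECTRONS_PER_O2 * lo, ELECTRONS_PER_O2 * hi


@dataclass(frozen=True)
class PECurve:
    """Exponential-saturation photosynthesis–irradiance curve.

    alpha: initial slope, mol C (mg chl a)-1 h-1 (umol quanta m-2 s-1)-1;
    Pmax: maximum rate, mol C (mg chl a)-1 h-1; Ek = Pmax/alpha.
    """

    alpha: float
    Pmax: float
    r_squared: Optional[float] = None

    def __post_init__(self):
        if self.alpha <= 0 or self.Pmax <= 0:
            raise ValueError("alpha and Pmax must be > 0")

    @property
    def Ek(self) -> float:
        return self.Pmax / self.alpha

    def __call__(self, E) -> np.ndarray | float:
        return evaluate_pe(self, E)


@dataclass(frozen=True)
class CarbonUptakeRecord:
    """Chlorophyll-normalised carbon uptake for one sample."""

    P_chla: float  #: mol C (mg chl a)-1 h-1
    chla: float    #: mg m-3
    provenance: str = "in_situ"  # {in_situ, simulated_in_situ, PE_curve, cuvette}
    incubation_hours: Optional[float] = None

    def __post_init__(self):
        if self.P_chla < 0:
            raise ValueError("P_chla must be >= 0")
        if self.chla <= 0:
            raise ValueError("chla must be > 0")


@dataclass(frozen=True)
class PhiRecord:
    """Electron requirement for carbon fixation with its light context."""

    phi_ec: float  #: mol e- (mol C)-1
    etr_variant: str
    in_observed_envelope: bool
    in_theoretical_band: bool
    E: Optional[float] = None
    Ek: Optional[float] = None
    E_to_Ek: Optional[float] = None


def _webb(E, Pmax, alpha):
    return Pmax * (1.0 - np.exp(-alpha * E / Pmax))


def fit_pe_curve(E_levels: Sequence[float], P_levels: Sequence[float]) -> PECurve:
    """Least-squares fit of P(E) = Pmax (1 - exp(-alpha E / Pmax)).

    Requires at least 4 (E, P) pairs with E >= 0, P >= 0. Raises on
    non-convergence or on an all-zero response.
    """
    E = np.asarray(E_levels, dtype=float)
    P = np.asarray(P_levels, dtype=float)
    if E.shape != P.shape or E.ndim != 1:
        raise ValueError("E and P must be 1-D and equal length")
    if E.size < 4:
        raise ValueError("need at least 4 (E, P) pairs")
    if np.any(E < 0) or np.any(P < 0):
        raise ValueError("E and P must be >= 0")
    if np.all(P == 0):
        raise ValueError("all-zero uptake: PE curve undefined")

    pmax0 = float(P.max())
    # initial slope from the lowest positive-irradiance point
    pos = E > 0
    alpha0 = float(np.median(P[pos] / E[pos])) if pos.any() else 1e-4
    alpha0 = max(alpha0, 1e-12)
    try:
        popt, _ = curve_fit(
            _webb, E, P, p0=[pmax0, alpha0],
            bounds=([1e-300, 1e-300], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise ValueError(f"PE fit did not converge: {exc}") from exc
    pmax, alpha = float(popt[0]), float(popt[1])
    resid = P - _webb(E, pmax, alpha)
    ss_tot = float(np.sum((P - P.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PECurve(alpha=alpha, Pmax=pmax, r_squared=r2)


def evaluate_pe(curve: PECurve, E) -> np.ndarray | float:
    """Evaluate the fitted PE curve at irradiance E (monotone, bounded by Pmax)."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("E must be >= 0")
    out = _webb(E, curve.Pmax, curve.alpha)
    return float(out) if out.ndim == 0 else out


def daily_to_hourly(P_daily: float, light_weights: Sequence[float]) -> np.ndarray:
    """Distribute a daily-integrated uptake over daylight hours.

    ``light_weights`` holds one non-negative fraction per daylight hour and
    must sum to 1 (tolerance 1e-6); hour h receives P_daily * weight[h], so
    the hourly rates sum back to the daily integral exactly.
    """
    w = np.asarray(light_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("light weights must be >= 0")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"light weights sum to {w.sum():.8f}, expected 1")
    return P_daily * w


def phi_ec(
    etr: ElectronTransportRecord | float,
    c: CarbonUptakeRecord | float,
    E: float | None = None,
    Ek: float | None = None,
) -> PhiRecord:
    """Electron requirement Phi_e,C = ETR / P_chla, mol e- (mol C)-1.

    Both rates must be chlorophyll-normalised and on the same hourly time
    base. Values outside the observed envelope [1, 60] are flagged; a zero
    uptake rate is an error (undefined ratio), never infinity.
    """
    if isinstance(etr, ElectronTransportRecord):
        etr_value, variant = etr.etr, etr.equation_variant
        if E is None:
            E = etr.E
    else:
        etr_value, variant = float(etr), "unspecified"
    p = c.P_chla if isinstance(c, CarbonUptakeRecord) else float(c)
    if p <= 0:
        raise ValueError("P_chla must be > 0: Phi_e,C undefined at zero uptake")
    if etr_value < 0:
        raise ValueError("ETR must be >= 0")
    phi = etr_value / p
    ratio = None
    if E is not None and Ek is not None and Ek > 0:
        ratio = E / Ek
    lo, hi = OBSERVED_ENVELOPE
    blo, bhi = THEORETICAL_BAND
    return PhiRecord(
        phi_ec=phi, etr_variant=variant,
        in_observed_envelope=lo <= phi <= hi,
        in_theoretical_band=blo <= phi <= bhi,
        E=E, Ek=Ek, E_to_Ek=ratio,
    )


def etr_to_carbon(etr: float, phi: float) -> float:
    """Convert an ETR to a carbon fixation rate: P = ETR / Phi_e,C.

    Exact inverse of :func:`phi_ec` for the same pair of rates.
    """
    if phi <= 0:
        raise ValueError("Phi_e,C must be > 0")
    if etr < 0:
        raise ValueError("ETR must be >= 0")
    return etr / phi
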