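"""Closed-form one-compartment pharmacokinetics and dose conversions.

These are the analytic solutions of the drug compartments of the dosed system
— iv bolus decay, the Bateman curve for ip absorption, and the constant-rate
infusion fixed point — used both as calibration targets and as independent
oracles for the numerical integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputDomainError

__all__ = [
    "DoseConversionContext",
    "iv_bolus_concentration",
    "ip_bateman_concentration",
    "bateman_peak_time",
    "dose_to_peritoneal_concentration",
    "half_life",
    "steady_state_infusion_concentration",
]

MINUTES_PER_DAY = 1440.0
MM3_PER_ML = 1000.0

#: Tolerance below which ka and kex are treated as equal and the limiting
#: form of the Bateman curve is used.
_BATEMAN_EQ_RTOL = 1e-9


@dataclass(frozen=True)
class DoseConversionContext:
    """Body-size assumptions for converting mg/kg doses to concentrations.

    Defaults: a 20 g mouse with a peritoneal cavity volume of 10 ml/kg.
    """

    body_weight: float = 0.02  # kg
    peritoneal_volume_per_kg: float = 10.0  # ml/kg

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.peritoneal_volume_per_kg <= 0:
            raise InputDomainError("body_weight and peritoneal_volume_per_kg must be > 0")


def iv_bolus_concentration(t, C0: float, kex: float):
    """Plasma concentration after an iv bolus: C0 * exp(-kex * t).

    First-order renal clearance from a single well-mixed compartment.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputDomainError("t must be >= 0")
    if C0 < 0 or kex < 0:
        raise InputDomainError("C0 and kex must be >= 0")
    out = C0 * np.exp(-kex * t)
    return out if out.ndim else float(out)


def ip_bateman_concentration(t, C0IP: float, ka: float, kex: float):
    """Plasma concentration after an ip bolus (Bateman function).

    First-order absorption from the peritoneal cavity (rate constant ``ka``)
    followed by first-order renal excretion (``kex``):

        C(t) = ka*C0IP/(ka - kex) * (exp(-kex*t) - exp(-ka*t))

    with the limit ``ka*C0IP*t*exp(-ka*t)`` when ka = kex (within relative
    tolerance 1e-9).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputDomainError("t must be >= 0")
    if ka <= 0 or kex <= 0:
        raise InputDomainError("ka and kex must be > 0")
    if C0IP < 0:
        raise InputDomainError("C0IP must be >= 0")
    if abs(ka - kex) < _BATEMAN_EQ_RTOL * ka:
        out = ka * C0IP * t * np.exp(-ka * t)
    else:
        out = ka * C0IP / (ka - kex) * (np.exp(-kex * t) - np.exp(-ka * t))
    return out if out.ndim else float(out)


def bateman_peak_time(ka: float, kex: float) -> float:
    """Time of maximum plasma concentration, ln(ka/kex)/(ka - kex)."""
    if ka <= 0 or kex <= 0:
        raise InputDomainError("ka and kex must be > 0")
    if abs(ka - kex) < _BATEMAN_EQ_RTOL * ka:
        return 1.0 / ka
    return float(np.log(ka / kex) / (ka - kex))


def dose_to_peritoneal_concentration(
    dose: float, ctx: DoseConversionContext = DoseConversionContext()
) -> float:
    """Convert an ip dose in mg/kg to the peritoneal concentration in mg/mm^3.

    Administered mass = dose * body_weight; distribution volume = peritoneal
    volume (ml/kg * body_weight), with 1 ml = 1000 mm^3. With the default
    mouse context, 80 mg/kg gives 0.008 mg/mm^3.
    """
    if dose < 0:
        raise InputDomainError("dose must be >= 0")
    mass_mg = dose * ctx.body_weight
    volume_mm3 = ctx.peritoneal_volume_per_kg * ctx.body_weight * MM3_PER_ML
    return mass_mg / volume_mm3


def half_life(kex: float) -> float:
    """Elimination half-life ln(2)/kex, expressed in minutes (kex in day^-1)."""
    if kex <= 0:
        raise InputDomainError("kex must be > 0")
    return float(np.log(2.0) / kex * MINUTES_PER_DAY)


def steady_state_infusion_concentration(mu: float, kex: float) -> float:
    """Asymptotic plasma concentration under constant-rate infusion.

    The infusion source term is mu*kex, so the fixed point of
    dC/dt = mu*kex - kex*C is mu itself: the infusion constant IS the
    asymptotic concentration.
    """
    if mu < 0:
        raise InputDomainError("mu must be >= 0")
    if kex <= 0:
        raise InputDomainError("kex must be > 0")
    return float(mu)
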