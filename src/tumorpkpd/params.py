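"""Model parameters, dose schedules and parameter-file I/O.

The model describes subcutaneous mammary-tumor growth in mice under two
therapies built around the TAM-targeting cyclic peptide CSSTRESAC:

* ligand-directed suicide gene therapy (peptide-displaying AAVP vector
  delivering HSVtk, activated by daily intraperitoneal ganciclovir), and
* systemic treatment with the soluble peptide.

Tumor volume follows logistic growth; the peptide contributes a saturable
(Michaelis-Menten) death term governed by the dissociation constant ``Kd`` of
the CSSTRESAC-DBP-PDIA3 complex, and ganciclovir (GCV) contributes a death
term linear in its plasma concentration. Drug concentrations follow
one-compartment first-order kinetics with impulsive dosing.

Units are carried as internally consistent labels: tumor volume in mm^3, time
in days, peptide plasma concentration in mM, GCV concentrations in mg/mm^3.
Only products of concentrations with their paired rate constants enter the
dynamics, so no inter-unit conversion is ever performed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import yaml

from .errors import ConfigurationError, InputDomainError

#: Compartments that can receive an impulsive dose.
Compartment = Literal["peptide_plasma", "gcv_peritoneal"]

#: Peptide clearance mode: AAVP-displayed peptide clears with ``kex_pep``,
#: the soluble peptide with the much faster ``kex_pep_sol``.
PeptideMode = Literal["aavp", "soluble"]

#: Whether tumor death terms scale with tumor volume (dimensionally consistent
#: default) or are taken literally as absolute rates.
DeathScaling = Literal["proportional", "absolute"]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and capacities of the tumor growth / PK system.

    Attributes
    ----------
    sigma : float
        Tumor growth rate constant (day^-1).
    K : float
        Carrying capacity of the host (mm^3).
    V0 : float
        Initial tumor volume at implantation, t = 0 (mm^3).
    D_pep : float
        Asymptotic peptide-induced death rate (day^-1); indicative of potency.
    Kd : float
        Dissociation constant of the CSSTRESAC-DBP-PDIA3 complex (mM, same
        units as the peptide plasma concentration). Implicitly reflects
        competitive antagonism by 1,25-(OH)2D3.
    lam : float
        Proportionality constant between GCV plasma concentration and death
        rate (day^-1 per mg/mm^3).
    kex_pep : float
        Excretion rate constant of the AAVP-displayed peptide (day^-1).
    kex_pep_sol : float
        Excretion rate constant of the soluble peptide (day^-1).
    ka_gcv : float
        GCV absorption rate constant, peritoneal cavity -> plasma (day^-1).
    kex_gcv : float
        GCV renal excretion rate constant (day^-1).
    """

    sigma: float
    K: float
    V0: float
    D_pep: float
    Kd: float
    lam: float
    kex_pep: float
    kex_pep_sol: float
    ka_gcv: float
    kex_gcv: float

    def __post_init__(self) -> None:
        rates = {
            "sigma": self.sigma,
            "D_pep": self.D_pep,
            "lam": self.lam,
            "kex_pep": self.kex_pep,
            "kex_pep_sol": self.kex_pep_sol,
            "ka_gcv": self.ka_gcv,
            "kex_gcv": self.kex_gcv,
        }
        for name, value in rates.items():
            if value < 0:
                raise InputDomainError(f"{name} must be >= 0, got {value}")
        if self.K <= 0:
            raise InputDomainError(f"K must be > 0, got {self.K}")
        if self.Kd <= 0:
            raise InputDomainError(f"Kd must be > 0, got {self.Kd}")
        if not 0 <= self.V0 < self.K:
            raise InputDomainError(
                f"V0 must satisfy 0 <= V0 < K, got V0={self.V0}, K={self.K}"
            )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ConfigurationError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class DoseEvent:
    """Instantaneous dose: the named compartment jumps by ``amount`` at ``time``.

    This realizes the impulsive-dosing limit exactly: integration stops at the
    event time, the concentration increment is added, and integration restarts.
    """

    time: float
    compartment: Compartment
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InputDomainError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise InputDomainError(f"dose amount must be >= 0, got {self.amount}")
        if self.compartment not in ("peptide_plasma", "gcv_peritoneal"):
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered impulsive dose events plus an optional constant-rate infusion.

    The infusion models constant-rate iv delivery of the soluble peptide: for
    t > ``infusion_start`` the peptide compartment gains ``mu * kex_pep_sol``
    per day, so its concentration relaxes to the asymptote ``infusion_mu``.
    ``infusion_mu = 0`` disables the infusion.
    """

    events: tuple[DoseEvent, ...] = ()
    infusion_mu: float = 0.0
    infusion_start: float = 5.0

    def __post_init__(self) -> None:
        if self.infusion_mu < 0:
            raise InputDomainError("infusion_mu must be >= 0")
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.time))
        )

    def event_times(self) -> list[float]:
        return [e.time for e in self.events]

    @staticmethod
    def empty() -> "DoseSchedule":
        return DoseSchedule(events=())


# Printed study doses: single peptide/vector bolus at day 5 (I1 = 0.8 mM) and
# daily ip GCV on days 12..21 inclusive (I0 = 0.008 mg/mm^3, ten doses,
# starting one week after vector administration).
PEPTIDE_BOLUS_DAY = 5.0
PEPTIDE_BOLUS_AMOUNT = 0.8  # mM
GCV_DOSE_DAYS = tuple(float(d) for d in range(12, 22))
GCV_DOSE_AMOUNT = 0.008  # mg/mm^3


def gene_therapy_schedule(
    peptide: bool = True,
    gcv: bool = True,
    peptide_amount: float = PEPTIDE_BOLUS_AMOUNT,
    gcv_amount: float = GCV_DOSE_AMOUNT,
) -> DoseSchedule:
    """Dose schedule of the mouse gene-therapy experiment.

    Vector (peptide) bolus at day 5, daily GCV on days 12-21.
    """
    events: list[DoseEvent] = []
    if peptide:
        events.append(DoseEvent(PEPTIDE_BOLUS_DAY, "peptide_plasma", peptide_amount))
    if gcv:
        events.extend(
            DoseEvent(day, "gcv_peritoneal", gcv_amount) for day in GCV_DOSE_DAYS
        )
    return DoseSchedule(events=tuple(events))


def soluble_peptide_schedule(
    days: Iterable[float] | None = None,
    amount: float = PEPTIDE_BOLUS_AMOUNT,
) -> DoseSchedule:
    """Daily iv boluses of the soluble peptide, days 5..21 by default."""
    if days is None:
        days = [float(d) for d in range(5, 22)]
    return DoseSchedule(
        events=tuple(DoseEvent(d, "peptide_plasma", amount) for d in days)
    )


DEFAULT_PARAMS_RESOURCE = "default_params.yaml"


def load_parameter_file(path: str | Path) -> tuple[ModelParameters, dict]:
    """Read a YAML parameter file.

    The file is a flat ``parameters:`` mapping with the exact field names of
    :class:`ModelParameters`, plus optional ``schedule`` and ``trial`` blocks.
    Returns the parameters and the full raw mapping (for schedule/trial use).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ConfigurationError(f"{path}: expected a top-level 'parameters' mapping")
    return ModelParameters.from_dict(raw["parameters"]), raw


def save_parameter_file(path: str | Path, params: ModelParameters, extra: dict | None = None) -> None:
    raw = dict(extra or {})
    raw["parameters"] = params.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """The packaged reference parameter set (see ``data/default_params.yaml``)."""
    with resources.files("tumorpkpd.data").joinpath(DEFAULT_PARAMS_RESOURCE).open() as fh:
        raw = yaml.safe_load(fh)
    return ModelParameters.from_dict(raw["parameters"])
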