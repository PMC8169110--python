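"""Forward simulation of treatment scenarios.

Covers the three in-silico experiments built on the calibrated model:

* the mouse gene-therapy experiment (GCV-only control, fd-AAVP-HSVtk + GCV,
  CSSTRESAC-AAVP-HSVtk + GCV) and the soluble-peptide treatment arms;
* the Kd sensitivity analysis (+/- 20 % perturbation of the dissociation
  constant, probing competitive antagonism by circulating vitamin D);
* the simulated human trial comparing a unit iv bolus of the soluble peptide
  against a constant-rate infusion with asymptote mu.

Arm semantics: the GCV kill term (lam) is active only where HSVtk was
delivered, i.e. in both AAVP arms but not in the GCV-only control; the
peptide kill term (D_pep) is active only where CSSTRESAC is present.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import io
from .dynamics import TrajectorySeries, simulate
from .errors import ConfigurationError, InputDomainError
from .params import (
    DeathScaling,
    DoseSchedule,
    ModelParameters,
    gene_therapy_schedule,
    soluble_peptide_schedule,
)

__all__ = [
    "TrialSettings",
    "simulate_arm",
    "arm_trajectory",
    "compare_bolus_vs_infusion",
    "kd_sensitivity",
    "simulate_gene_therapy_experiment",
]

DEFAULT_HORIZON = 60.0  # days; end of the projected human-trial window
DEFAULT_INFUSION_MU = 0.75  # mM
DEFAULT_BOLUS_AMOUNT = 1.0  # mM, the "unit" iv bolus


@dataclass(frozen=True)
class TrialSettings:
    """One arm of the simulated human trial.

    ``bolus`` mode administers a single iv bolus of ``bolus_amount`` at
    ``infusion_start``; ``infusion`` mode switches on a constant-rate infusion
    with asymptotic concentration ``mu`` at the same time. Both use soluble
    peptide kinetics (``kex_pep_sol``); GCV plays no role in this scenario.
    """

    params: ModelParameters
    mode: str = "bolus"  # "bolus" | "infusion"
    mu: float = DEFAULT_INFUSION_MU
    bolus_amount: float = DEFAULT_BOLUS_AMOUNT
    start: float = 5.0
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if self.mode not in ("bolus", "infusion"):
            raise ConfigurationError(f"unknown trial mode {self.mode!r}")
        if self.mu < 0 or self.bolus_amount < 0:
            raise InputDomainError("mu and bolus_amount must be >= 0")
        if self.horizon <= self.start:
            raise InputDomainError("horizon must exceed the treatment start")

    def schedule(self) -> DoseSchedule:
        if self.mode == "bolus":
            if self.bolus_amount > 0:
                return soluble_peptide_schedule(days=[self.start], amount=self.bolus_amount)
            return DoseSchedule.empty()
        return DoseSchedule(events=(), infusion_mu=self.mu, infusion_start=self.start)


def simulate_arm(
    settings: TrialSettings,
    scaling: DeathScaling = "proportional",
    t_eval: np.ndarray | None = None,
) -> TrajectorySeries:
    """Trajectory of one trial arm from t = 0 to the horizon."""
    params = settings.params.replace(lam=0.0)  # no GCV in the peptide trial
    return simulate(
        params,
        settings.schedule(),
        t_span=(0.0, settings.horizon),
        mode="soluble",
        scaling=scaling,
        t_eval=t_eval,
    )


def compare_bolus_vs_infusion(
    bolus: TrialSettings,
    infusion: TrialSettings,
    scaling: DeathScaling = "proportional",
) -> float:
    """V_bolus(horizon) - V_infusion(horizon), in mm^3.

    Positive values mean the infusion regimen left a smaller tumor, i.e.
    infusion is superior. Both arms must share parameters and horizon.
    """
    if bolus.params != infusion.params:
        raise ConfigurationError("trial arms must share model parameters")
    if bolus.horizon != infusion.horizon:
        raise ConfigurationError("trial arms must share the simulation horizon")
    vb = simulate_arm(bolus, scaling).V[-1]
    vi = simulate_arm(infusion, scaling).V[-1]
    return float(vb - vi)


def kd_sensitivity(
    settings: TrialSettings,
    perturbation: float = 0.20,
    scaling: DeathScaling = "proportional",
) -> dict[str, float]:
    """Final tumor volumes with Kd perturbed by -/0/+ ``perturbation``.

    A larger Kd mimics stronger competitive antagonism (weaker peptide
    binding, less tumor kill); a smaller Kd mimics tighter binding. Returns
    ``{"-20%": V, "ref": V, "+20%": V}`` (labels follow the perturbation).
    """
    if perturbation < 0 or perturbation >= 1:
        raise InputDomainError("perturbation must lie in [0, 1)")
    out: dict[str, float] = {}
    pct = int(round(100 * perturbation))
    for label, factor in ((f"-{pct}%", 1 - perturbation), ("ref", 1.0), (f"+{pct}%", 1 + perturbation)):
        p = settings.params.replace(Kd=settings.params.Kd * factor)
        traj = simulate_arm(dataclasses.replace(settings, params=p), scaling)
        out[label] = float(traj.V[-1])
    return out


#: Dynamics of each experimental arm: (peptide kill active, GCV kill active,
#: peptide dosing, GCV dosing, peptide clearance mode).
_ARM_SPECS: dict[str, dict] = {
    # Gene-therapy experiment: vector at day 5, daily GCV days 12-21.
    "control_gcv_only": dict(peptide=False, hsvtk=False, gcv=True, mode="aavp"),
    "fd_aavp_gcv": dict(peptide=False, hsvtk=True, gcv=True, mode="aavp"),
    "csstresac_aavp_gcv": dict(peptide=True, hsvtk=True, gcv=True, mode="aavp"),
    # Soluble-peptide experiment: daily iv peptide days 5-21, no GCV.
    "vehicle": dict(peptide=False, hsvtk=False, gcv=False, mode="soluble"),
    "control_peptide": dict(peptide=False, hsvtk=False, gcv=False, mode="soluble"),
    "soluble_csstresac": dict(peptide=True, hsvtk=False, gcv=False, mode="soluble"),
}


def arm_trajectory(
    params: ModelParameters,
    arm: str,
    t_span: tuple[float, float] = (0.0, 21.0),
    t_eval: np.ndarray | None = None,
    scaling: DeathScaling = "proportional",
) -> TrajectorySeries:
    """Deterministic model trajectory for one experimental arm.

    Kill-term activity follows the arm's biology: ``lam`` requires HSVtk
    delivery (either AAVP vector), ``D_pep`` requires CSSTRESAC (displayed on
    the vector or soluble). Control arms therefore reduce to pure logistic
    growth even when drugs are administered.
    """
    if arm not in _ARM_SPECS:
        raise ConfigurationError(f"unknown arm label {arm!r}; known: {sorted(_ARM_SPECS)}")
    spec = _ARM_SPECS[arm]
    p = params
    if not spec["peptide"]:
        p = p.replace(D_pep=0.0)
    if not spec["hsvtk"]:
        p = p.replace(lam=0.0)
    if spec["mode"] == "aavp":
        schedule = gene_therapy_schedule(peptide=spec["peptide"], gcv=spec["gcv"])
    else:
        if spec["peptide"]:
            schedule = soluble_peptide_schedule()
        else:
            schedule = DoseSchedule.empty()
    return simulate(p, schedule, t_span=t_span, mode=spec["mode"], t_eval=t_eval, scaling=scaling)


def simulate_gene_therapy_experiment(
    params: ModelParameters,
    arms: tuple[str, ...] = ("control_gcv_only", "fd_aavp_gcv", "csstresac_aavp_gcv"),
    t_span: tuple[float, float] = (0.0, 21.0),
    scaling: DeathScaling = "proportional",
) -> dict[str, TrajectorySeries]:
    """Per-arm trajectories of the mouse experiment (day 0-21 by default)."""
    for arm in arms:
        if arm not in io.ARMS:
            raise ConfigurationError(f"unknown arm label {arm!r}")
    return {arm: arm_trajectory(params, arm, t_span=t_span, scaling=scaling) for arm in arms}
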