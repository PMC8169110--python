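"""Right-hand side and integrator for the dosed tumor-growth ODE system.

State vector: ``y = (V, c_pep_p, c_gcv_p, c_gcv_ip)`` — tumor volume (mm^3),
peptide plasma concentration (mM), GCV plasma and peritoneal concentrations
(mg/mm^3). The tumor balance is

    dV/dt = G - S - N

with logistic proliferation G = sigma*V*(1 - V/K), a saturable peptide kill
term S, and a GCV kill term N linear in plasma concentration. As printed, the
kill expressions D_pep*c/(c+Kd) and lam*c carry units of day^-1 and cannot be
subtracted from a mm^3/day growth term; the default ``proportional`` scaling
therefore multiplies both by V (per-volume death rates), the standard
convention in logistic tumor-kill models. ``absolute`` preserves the literal
reading for comparison.

Dosing is impulsive: integration halts at each dose time, the named
compartment jumps by the dose amount, and integration restarts — an exact
realization of the eps -> 0 limit construction, with no solver event-root
ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InputDomainError
from .params import DeathScaling, DoseSchedule, ModelParameters, PeptideMode

__all__ = [
    "RateTerms",
    "SystemState",
    "TrajectorySeries",
    "logistic_growth_rate",
    "peptide_death_rate",
    "gcv_death_rate",
    "rhs",
    "logistic_closed_form",
    "simulate",
]

#: Default integrator settings. kex_pep_sol = 38 day^-1 makes the peptide
#: compartment fast relative to tumor dynamics, so an implicit-capable
#: adaptive method (LSODA) with tight tolerances is the default.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_GRID_STEP = 0.1  # days


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state of the coupled tumor/PK system."""

    t: float
    V: float
    c_pep_p: float
    c_gcv_p: float
    c_gcv_ip: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.c_pep_p, self.c_gcv_p, self.c_gcv_ip])


@dataclass(frozen=True)
class RateTerms:
    """The three tumor-balance contributions, each in mm^3/day."""

    G: float
    S: float
    N: float


@dataclass(frozen=True)
class TrajectorySeries:
    """A solved trajectory on a strictly increasing time grid."""

    times: np.ndarray
    V: np.ndarray
    c_pep_p: np.ndarray
    c_gcv_p: np.ndarray
    c_gcv_ip: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise InputDomainError("trajectory times must be strictly increasing")

    def state_at(self, i: int) -> SystemState:
        return SystemState(
            t=float(self.times[i]),
            V=float(self.V[i]),
            c_pep_p=float(self.c_pep_p[i]),
            c_gcv_p=float(self.c_gcv_p[i]),
            c_gcv_ip=float(self.c_gcv_ip[i]),
        )

    def volume_at(self, days: np.ndarray | list[float]) -> np.ndarray:
        """Linear interpolation of tumor volume at the requested days."""
        return np.interp(np.asarray(days, dtype=float), self.times, self.V)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.times,
                "volume_mm3": self.V,
                "c_pep": self.c_pep_p,
                "c_gcv_p": self.c_gcv_p,
                "c_gcv_ip": self.c_gcv_ip,
            }
        )


def logistic_growth_rate(V: float, sigma: float, K: float) -> float:
    """Logistic proliferation rate G = sigma * V * (1 - V/K), in mm^3/day.

    V = 0 (no cells) and V = K (carrying capacity) are valid absorbing /
    equilibrium inputs, both returning 0.
    """
    if V < 0:
        raise InputDomainError(f"V must be >= 0, got {V}")
    if sigma < 0:
        raise InputDomainError(f"sigma must be >= 0, got {sigma}")
    if K <= 0:
        raise InputDomainError(f"K must be > 0, got {K}")
    return sigma * V * (1.0 - V / K)


def peptide_death_rate(
    V: float,
    c_pep: float,
    D_pep: float,
    Kd: float,
    scaling: DeathScaling = "proportional",
) -> float:
    """Peptide-induced death term S (mm^3/day), saturable in concentration.

    Michaelis-Menten in the peptide plasma concentration: half the asymptotic
    death rate ``D_pep`` is reached at ``c_pep = Kd``; ``D_pep`` itself is the
    kill rate at saturating peptide.
    """
    if Kd <= 0:
        raise InputDomainError(f"Kd must be > 0, got {Kd}")
    if min(V, c_pep, D_pep) < 0:
        raise InputDomainError("V, c_pep and D_pep must all be >= 0")
    per_volume = D_pep * c_pep / (c_pep + Kd)
    return V * per_volume if scaling == "proportional" else per_volume


def gcv_death_rate(
    V: float,
    c_gcv: float,
    lam: float,
    scaling: DeathScaling = "proportional",
) -> float:
    """GCV-induced death term N (mm^3/day), linear in plasma concentration."""
    if min(V, c_gcv, lam) < 0:
        raise InputDomainError("V, c_gcv and lam must all be >= 0")
    per_volume = lam * c_gcv
    return V * per_volume if scaling == "proportional" else per_volume


def rate_terms(
    state: SystemState,
    params: ModelParameters,
    scaling: DeathScaling = "proportional",
) -> RateTerms:
    """Evaluate the three tumor-balance terms at a state."""
    return RateTerms(
        G=logistic_growth_rate(state.V, params.sigma, params.K),
        S=peptide_death_rate(state.V, state.c_pep_p, params.D_pep, params.Kd, scaling),
        N=gcv_death_rate(state.V, state.c_gcv_p, params.lam, scaling),
    )


def _infusion_rate(t: float, params: ModelParameters, schedule: DoseSchedule) -> float:
    # I(t) = 0 for t <= infusion_start, mu * kex_pep_sol after: the peptide
    # compartment then relaxes to the asymptote mu.
    if schedule.infusion_mu > 0 and t > schedule.infusion_start:
        return schedule.infusion_mu * params.kex_pep_sol
    return 0.0


def rhs(
    t: float,
    y: np.ndarray,
    params: ModelParameters,
    schedule: DoseSchedule,
    mode: PeptideMode = "aavp",
    scaling: DeathScaling = "proportional",
) -> np.ndarray:
    """Time derivatives of ``(V, c_pep_p, c_gcv_p, c_gcv_ip)``.

    ``mode`` selects which excretion constant governs the peptide compartment:
    the AAVP-displayed peptide (``kex_pep``) or the soluble peptide
    (``kex_pep_sol``). The infusion source term, when active, always uses
    ``kex_pep_sol`` (only the soluble peptide is infused).
    """
    V, c_pep, c_gcv_p, c_gcv_ip = y
    kex = params.kex_pep if mode == "aavp" else params.kex_pep_sol

    # Clamp tiny negative excursions from the integrator.
    Vp = max(V, 0.0)
    cp = max(c_pep, 0.0)
    cgp = max(c_gcv_p, 0.0)
    cgi = max(c_gcv_ip, 0.0)

    G = logistic_growth_rate(Vp, params.sigma, params.K)
    S = peptide_death_rate(Vp, cp, params.D_pep, params.Kd, scaling)
    N = gcv_death_rate(Vp, cgp, params.lam, scaling)
    dV = G - S - N
    if scaling == "absolute" and Vp <= 0.0 and dV < 0.0:
        dV = 0.0  # literal reading would push V negative; hold at zero

    return np.array(
        [
            dV,
            _infusion_rate(t, params, schedule) - kex * cp,
            params.ka_gcv * cgi - params.kex_gcv * cgp,
            -params.ka_gcv * cgi,
        ]
    )


def logistic_closed_form(
    t: np.ndarray | float, V0: float, sigma: float, K: float
) -> np.ndarray | float:
    """Closed-form logistic solution K*V0*e^{sigma t} / (K + V0*(e^{sigma t}-1))."""
    e = np.exp(sigma * np.asarray(t, dtype=float))
    out = K * V0 * e / (K + V0 * (e - 1.0))
    return out if np.ndim(t) else float(out)


def simulate(
    params: ModelParameters,
    schedule: DoseSchedule,
    t_span: tuple[float, float] = (0.0, 21.0),
    mode: PeptideMode = "aavp",
    scaling: DeathScaling = "proportional",
    y0: np.ndarray | None = None,
    t_eval: np.ndarray | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> TrajectorySeries:
    """Integrate the dosed system over ``t_span``.

    Integration proceeds segment-by-segment between dose events (and the
    infusion switch-on), applying each dose as a hard state jump. Output is
    sampled on ``t_eval`` if given, else on a uniform grid of ``grid_step``.

    Raises
    ------
    RuntimeError
        If the integrator fails; the message includes the last good state.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise InputDomainError("t_span must have t1 > t0")
    if y0 is None:
        y0 = np.array([params.V0, 0.0, 0.0, 0.0])
    y = np.asarray(y0, dtype=float).copy()
    if np.any(y < 0):
        raise InputDomainError("initial state must be non-negative")

    if t_eval is None:
        n = int(round((t1 - t0) / grid_step))
        t_eval = np.linspace(t0, t1, n + 1)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval[0] < t0 or t_eval[-1] > t1:
            raise InputDomainError("t_eval must lie within t_span")

    # Breakpoints: dose events inside the span, plus the infusion switch-on
    # (the source term is discontinuous there).
    breaks = {e.time for e in schedule.events if t0 < e.time < t1}
    if schedule.infusion_mu > 0 and t0 < schedule.infusion_start < t1:
        breaks.add(schedule.infusion_start)
    edges = [t0, *sorted(breaks), t1]

    # Doses exactly at t0 are applied before integration starts.
    comp_index = {"peptide_plasma": 1, "gcv_peritoneal": 3}
    for e in schedule.events:
        if e.time == t0:
            y[comp_index[e.compartment]] += e.amount

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    for a, b in zip(edges[:-1], edges[1:]):
        # Half-open sampling [a, b) except the final segment includes b.
        last = b == t1
        mask = (t_eval >= a) & ((t_eval <= b) if last else (t_eval < b))
        seg_eval = np.unique(np.concatenate([t_eval[mask], [b]]))
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=seg_eval,
            rtol=rtol,
            atol=atol,
            args=(params, schedule, mode, scaling),
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed on [{a}, {b}]: {sol.message}; "
                f"last good state t={sol.t[-1] if sol.t.size else a}, "
                f"y={sol.y[:, -1] if sol.t.size else y}"
            )
        keep = sol.t < b if not last else slice(None)
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()
        np.maximum(y, 0.0, out=y)
        for e in schedule.events:
            if e.time == b:
                y[comp_index[e.compartment]] += e.amount

    t_all = np.concatenate(times_out)
    y_all = np.clip(np.concatenate(states_out, axis=1), 0.0, None)
    # A dose exactly at the horizon: report the post-jump state at t1, matching
    # the convention at interior event times (y already carries the jump).
    if t_all.size and t_all[-1] == t1:
        y_all[:, -1] = y
    # Keep only the requested grid (segment ends were added for continuity).
    sel = np.isin(t_all, t_eval)
    t_all, y_all = t_all[sel], y_all[:, sel]
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = y_all[:, idx]
    return TrajectorySeries(
        times=t_all, V=y_all[0], c_pep_p=y_all[1], c_gcv_p=y_all[2], c_gcv_ip=y_all[3]
    )
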