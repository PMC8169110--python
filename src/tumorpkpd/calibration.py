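"""Sequential nonlinear least-squares calibration of the tumor-growth model.

The estimation follows the study's staged procedure, each stage consuming
only previously estimated parameters:

1. ``fit_growth_rate`` — sigma from the GCV-only control arm, logistic model,
   observation window days 15-21 (kill terms ignored: GCV alone, without the
   HSVtk transgene, does not kill).
2. ``extrapolate_initial_volume`` — V0 by running the logistic closed form
   backward from the earliest fitted point to t = 0.
3. ``fit_gcv_pk`` — (ka_gcv, kex_gcv) from GCV plasma concentrations after an
   ip dose (Bateman curve).
4. ``fit_gcv_death`` — lam from the fd-AAVP-HSVtk + GCV arm with the peptide
   term held at zero, full system solved over days 0-21.
5. ``fit_peptide_params`` — (D_pep, Kd, kex_pep) jointly from the
   CSSTRESAC-AAVP-HSVtk + GCV arm, whole system active.
6. ``refit_soluble_excretion`` — kex_pep_sol from the soluble-peptide arm
   (the displayed and soluble peptides clear at very different rates).

All stages fit per-day arm means by ordinary least squares (optionally
weighted by 1/SD^2 when summaries carry SDs), using bounded trust-region
least squares; the three-parameter peptide stage uses Latin-hypercube
multi-start because its loss surface has identifiability plateaus when Kd
lies far above the peak plasma concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats.qmc import LatinHypercube

from . import io
from .dynamics import TrajectorySeries, logistic_closed_form, simulate
from .errors import CalibrationError, InputDomainError
from .params import PEPTIDE_BOLUS_AMOUNT, ModelParameters
from .pk import ip_bateman_concentration
from .trial import arm_trajectory

__all__ = [
    "FitResult",
    "fit_growth_rate",
    "extrapolate_initial_volume",
    "fit_gcv_pk",
    "fit_gcv_death",
    "fit_peptide_params",
    "refit_soluble_excretion",
    "fit_quality",
]

DEFAULT_SEED = 20210601
SIGMA_WINDOW = (15.0, 21.0)
FIT_SPAN = (0.0, 21.0)

# Optimizer bounds (day^-1 except Kd, which shares the peptide's
# concentration units).
SIGMA_BOUNDS = (1e-6, 5.0)
LAM_BOUNDS = (0.0, 1e3)
DPEP_BOUNDS = (0.0, 1e3)
KD_BOUNDS = (1e-6, 1e3)
KEX_BOUNDS = (1e-6, 1e3)


@dataclass
class FitResult:
    """Outcome of one calibration stage."""

    stage: str
    params: dict[str, float]
    rss: float
    converged: bool
    n_obs: int
    r: float | None = None
    p: float | None = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise InputDomainError("RSS must be >= 0")
        if self.r is not None and not -1.0000001 <= self.r <= 1.0000001:
            raise InputDomainError("Pearson R must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params,
            "rss": self.rss,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "r": self.r,
            "p": self.p,
            "message": self.message,
        }


def _arm_means_or_raise(df: pd.DataFrame, arm: str, stage: str) -> pd.DataFrame:
    io.validate_cohort(df)
    if arm not in set(df["arm"].unique()):
        raise CalibrationError(stage, f"required arm {arm!r} absent from data")
    return io.arm_means(df, arm)


def _weights(df: pd.DataFrame, arm: str, days: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "ols":
        return np.ones_like(days, dtype=float)
    summary = io.summarize_cohort(df)
    sub = summary[summary["arm"] == arm].set_index("day").reindex(days)
    sd = sub["sd_mm3"].to_numpy(dtype=float)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        raise CalibrationError("weights", "inverse-variance weighting needs positive per-day SDs")
    return 1.0 / sd


def fit_growth_rate(
    control_data: pd.DataFrame,
    arm: str = "control_gcv_only",
    window: tuple[float, float] = SIGMA_WINDOW,
    K: float = 1.0e4,
    weights: str = "ols",
) -> tuple[float, FitResult]:
    """Estimate sigma from control-arm means on the day 15-21 window.

    Fits the two parameters (sigma, V at the first window day) of the
    logistic closed form; the anchor volume is reported in the result so V0
    can be extrapolated from the earliest *fitted* point.
    """
    stage = "fit_growth_rate"
    means = _arm_means_or_raise(control_data, arm, stage)
    lo, hi = window
    means = means[(means["day"] >= lo) & (means["day"] <= hi)]
    if means["day"].nunique() < 2:
        raise CalibrationError(stage, f"need >= 2 time points in [{lo}, {hi}] days")
    days = means["day"].to_numpy(dtype=float)
    vols = means["volume_mm3"].to_numpy(dtype=float)
    w = _weights(control_data, arm, days, weights)
    t_ref = days[0]

    def resid(x):
        sigma, v_ref = x
        return w * (logistic_closed_form(days - t_ref, v_ref, sigma, K) - vols)

    x0 = np.array([0.3, max(vols[0], 1.0)])
    sol = least_squares(
        resid, x0, bounds=([SIGMA_BOUNDS[0], 1e-6], [SIGMA_BOUNDS[1], K * (1 - 1e-9)])
    )
    sigma, v_ref = float(sol.x[0]), float(sol.x[1])
    result = FitResult(
        stage=stage,
        params={"sigma": sigma, "anchor_day": float(t_ref), "anchor_volume": v_ref},
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        n_obs=len(days),
    )
    return sigma, result


def extrapolate_initial_volume(
    sigma: float,
    control_data: pd.DataFrame | None = None,
    K: float = 1.0e4,
    arm: str = "control_gcv_only",
    anchor: tuple[float, float] | None = None,
) -> float:
    """Extrapolate tumor volume back to implantation (t = 0).

    Inverts the logistic closed form from an anchor point (day, volume) — by
    default the earliest observed control-arm mean, or the fitted anchor from
    :func:`fit_growth_rate` when supplied.
    """
    stage = "extrapolate_initial_volume"
    if anchor is None:
        if control_data is None:
            raise CalibrationError(stage, "need control data or an explicit anchor")
        means = _arm_means_or_raise(control_data, arm, stage)
        row = means.iloc[means["day"].to_numpy().argmin()]
        anchor = (float(row["day"]), float(row["volume_mm3"]))
    t1, v1 = anchor
    if v1 >= K:
        raise InputDomainError(f"anchor volume {v1} must lie below the carrying capacity {K}")
    if v1 <= 0:
        raise InputDomainError("anchor volume must be > 0")
    # V0 = V*K / (K*e^{sigma t} - V*(e^{sigma t} - 1))
    e = np.exp(sigma * t1)
    return float(v1 * K / (K * e - v1 * (e - 1.0)))


def _bateman_heuristic_start(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Rough (ka, kex) from peak position and terminal log-slope."""
    i_peak = int(np.argmax(c))
    tail = slice(max(i_peak + 1, len(t) - 3), len(t))
    tt, cc = t[tail], c[tail]
    pos = cc > 0
    if pos.sum() >= 2:
        slope = np.polyfit(tt[pos], np.log(cc[pos]), 1)[0]
        kex0 = max(-slope, 1e-3)
    else:
        kex0 = 1.0 / max(t[-1], 1e-6)
    t_peak = max(t[i_peak], t[0])
    # Solve ln(ka/kex) / (ka - kex) = t_peak crudely: try ka on a log grid.
    kas = np.geomspace(kex0 * 1.01, kex0 * 1e3, 64)
    tp = np.log(kas / kex0) / (kas - kex0)
    ka0 = float(kas[np.argmin(np.abs(tp - t_peak))])
    return ka0, kex0


def fit_gcv_pk(
    pk_data: pd.DataFrame,
    C0IP: float,
    amplitude: str = "free",
) -> tuple[float, float, FitResult]:
    """Fit the Bateman curve to post-dose plasma concentrations.

    Returns (ka, kex, result). The absorption/excretion exchange ambiguity is
    resolved by the constraint ka > kex (flip-absorption convention): a fit
    landing at ka < kex is relabelled, rescaling the amplitude so the curve
    is unchanged. ``amplitude="free"`` (default) co-estimates a scale factor
    absorbing the unknown plasma volume of distribution / bioavailability;
    ``"fixed"`` pins the amplitude to the nominal peritoneal dose C0IP.
    """
    stage = "fit_gcv_pk"
    t = pk_data["day"].to_numpy(dtype=float)
    c = pk_data["concentration"].to_numpy(dtype=float)
    post = t > 0
    if post.sum() < 4:
        raise CalibrationError(stage, "need >= 4 post-dose samples spanning the peak")
    signs = np.sign(np.diff(c[post]))
    if np.count_nonzero(np.diff(signs[signs != 0])) > 1:
        warnings.warn("PK series is not unimodal; Bateman fit may be poor", stacklevel=2)

    free_amp = amplitude == "free"

    def model(x):
        ka, kex = x[0], x[1]
        scale = x[2] if free_amp else 1.0
        return scale * ip_bateman_concentration(t, C0IP, ka, kex)

    ka0, kex0 = _bateman_heuristic_start(t[post], c[post])
    best = None
    starts = [(ka0, kex0)] + [(ka0 * f, kex0 / f) for f in (3.0, 10.0)]
    for ka_s, kex_s in starts:
        x0 = [ka_s, kex_s] + ([1.0] if free_amp else [])
        lb = [1e-6, 1e-6] + ([1e-9] if free_amp else [])
        ub = [1e4, 1e4] + ([1e6] if free_amp else [])
        sol = least_squares(lambda x: model(x) - c, x0, bounds=(lb, ub))
        if best is None or sol.cost < best.cost:
            best = sol
    ka, kex = float(best.x[0]), float(best.x[1])
    scale = float(best.x[2]) if free_amp else 1.0
    if kex > ka:  # relabel under the exchange symmetry, curve unchanged
        ka, kex, scale = kex, ka, scale * kex / ka
    result = FitResult(
        stage=stage,
        params={"ka_gcv": ka, "kex_gcv": kex, "amplitude_scale": scale},
        rss=float(2 * best.cost),
        converged=bool(best.success),
        n_obs=len(t),
    )
    return ka, kex, result


def _simulated_arm_volumes(
    params: ModelParameters, arm: str, days: np.ndarray
) -> np.ndarray:
    traj = arm_trajectory(params, arm, t_span=(FIT_SPAN[0], float(days[-1])), t_eval=days)
    return traj.V


def fit_gcv_death(
    fd_aavp_data: pd.DataFrame,
    sigma: float,
    V0: float,
    gcv_pk: tuple[float, float],
    base_params: ModelParameters,
    weights: str = "ols",
) -> tuple[float, FitResult]:
    """Estimate lam from the fd-AAVP-HSVtk + GCV arm (peptide term off).

    The full dosed system is solved over days 0-21 with S = 0 and the GCV
    kill proportionality lam as the single free parameter.
    """
    stage = "fit_gcv_death"
    arm = "fd_aavp_gcv"
    means = _arm_means_or_raise(fd_aavp_data, arm, stage)
    days = means["day"].to_numpy(dtype=float)
    vols = means["volume_mm3"].to_numpy(dtype=float)
    w = _weights(fd_aavp_data, arm, days, weights)
    ka, kex_gcv = gcv_pk
    base = base_params.replace(sigma=sigma, V0=V0, D_pep=0.0, ka_gcv=ka, kex_gcv=kex_gcv)

    def resid(x):
        p = base.replace(lam=float(x[0]))
        return w * (_simulated_arm_volumes(p, arm, days) - vols)

    best = None
    for lam0 in (0.1, 1.0, 10.0, 100.0):
        sol = least_squares(resid, [lam0], bounds=([LAM_BOUNDS[0]], [LAM_BOUNDS[1]]))
        if best is None or sol.cost < best.cost:
            best = sol
    lam = float(best.x[0])
    message = ""
    if lam >= 0.999 * LAM_BOUNDS[1]:
        message = "lambda driven to upper bound; fit not converged in the interior"
    result = FitResult(
        stage=stage,
        params={"lam": lam},
        rss=float(2 * best.cost),
        converged=bool(best.success) and not message,
        n_obs=len(days),
        message=message,
    )
    return lam, result


def fit_peptide_params(
    treated_data: pd.DataFrame,
    sigma: float,
    V0: float,
    lam: float,
    gcv_pk: tuple[float, float],
    base_params: ModelParameters,
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
    weights: str = "ols",
) -> tuple[dict[str, float], FitResult]:
    """Joint (D_pep, Kd, kex_pep) fit on the CSSTRESAC-AAVP-HSVtk + GCV arm.

    Whole system solved over days 0-21 with every previously estimated
    parameter fixed. Multi-start (Latin hypercube in log10 space) bounded
    least squares; when the fitted Kd lies far above the peak peptide
    concentration the triple is only curve-level identifiable and the result
    is flagged.
    """
    stage = "fit_peptide_params"
    arm = "csstresac_aavp_gcv"
    means = _arm_means_or_raise(treated_data, arm, stage)
    days = means["day"].to_numpy(dtype=float)
    vols = means["volume_mm3"].to_numpy(dtype=float)
    w = _weights(treated_data, arm, days, weights)
    ka, kex_gcv = gcv_pk
    base = base_params.replace(sigma=sigma, V0=V0, lam=lam, ka_gcv=ka, kex_gcv=kex_gcv)

    def resid(x):
        d_pep, kd, kex = np.power(10.0, x)
        p = base.replace(D_pep=d_pep, Kd=kd, kex_pep=kex)
        return w * (_simulated_arm_volumes(p, arm, days) - vols)

    # log10 sampling boxes for (D_pep, Kd, kex_pep)
    lo = np.array([-3.0, -2.0, -2.0])
    hi = np.array([1.0, 1.0, 2.0])
    lhs = LatinHypercube(d=3, seed=seed).random(n=n_starts)
    starts = lo + lhs * (hi - lo)
    bounds = (
        np.log10([max(DPEP_BOUNDS[0], 1e-8), KD_BOUNDS[0], KEX_BOUNDS[0]]),
        np.log10([DPEP_BOUNDS[1], KD_BOUNDS[1], KEX_BOUNDS[1]]),
    )
    best = None
    for x0 in starts:
        sol = least_squares(resid, x0, bounds=bounds, x_scale="jac")
        if best is None or sol.cost < best.cost:
            best = sol
    d_pep, kd, kex = (float(v) for v in np.power(10.0, best.x))
    peak_c = PEPTIDE_BOLUS_AMOUNT  # peak plasma concentration after the bolus
    message = ""
    if kd > 50 * peak_c:
        message = (
            "Kd far above peak peptide concentration: (D_pep, Kd) only their "
            "ratio is identified (curve-level fit)"
        )
    params = {"D_pep": d_pep, "Kd": kd, "kex_pep": kex}
    result = FitResult(
        stage=stage,
        params=params,
        rss=float(2 * best.cost),
        converged=bool(best.success),
        n_obs=len(days),
        message=message,
    )
    return params, result


def refit_soluble_excretion(
    soluble_data: pd.DataFrame,
    sigma: float,
    V0: float,
    D_pep: float,
    Kd: float,
    base_params: ModelParameters,
    weights: str = "ols",
) -> tuple[float, FitResult]:
    """Refit the excretion rate of the *soluble* peptide on its treatment arm.

    The displayed peptide rides on the AAVP particle and clears slowly; the
    soluble peptide clears in minutes. With (D_pep, Kd) fixed from the gene
    therapy calibration, kex_pep_sol is the single free parameter; no GCV is
    given in this experiment, so the lam term is absent.
    """
    stage = "refit_soluble_excretion"
    arm = "soluble_csstresac"
    means = _arm_means_or_raise(soluble_data, arm, stage)
    days = means["day"].to_numpy(dtype=float)
    vols = means["volume_mm3"].to_numpy(dtype=float)
    w = _weights(soluble_data, arm, days, weights)
    base = base_params.replace(sigma=sigma, V0=V0, D_pep=D_pep, Kd=Kd, lam=0.0)

    def resid(x):
        p = base.replace(kex_pep_sol=float(np.power(10.0, x[0])))
        return w * (_simulated_arm_volumes(p, arm, days) - vols)

    best = None
    for k0 in (0.5, 5.0, 50.0, 500.0):
        sol = least_squares(
            resid,
            [np.log10(k0)],
            bounds=([np.log10(KEX_BOUNDS[0])], [np.log10(KEX_BOUNDS[1])]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    kex_sol = float(np.power(10.0, best.x[0]))
    message = ""
    if kex_sol >= 0.99 * KEX_BOUNDS[1]:
        message = (
            "kex_pep_sol at upper bound: the arm is indistinguishable from "
            "vehicle (instantly cleared drug has no effect)"
        )
    result = FitResult(
        stage=stage,
        params={"kex_pep_sol": kex_sol},
        rss=float(2 * best.cost),
        converged=bool(best.success) and not message,
        n_obs=len(days),
        message=message,
    )
    return kex_sol, result


def fit_quality(
    model_volumes: np.ndarray | TrajectorySeries,
    data: pd.DataFrame,
    arm: str = "csstresac_aavp_gcv",
) -> tuple[float, float]:
    """Pearson correlation between model predictions and observed arm means.

    ``model_volumes`` is either a trajectory (interpolated at the observation
    days) or an array aligned with the arm's observation days. Returns
    (R, two-sided p). Requires >= 3 matched pairs and non-degenerate variance.
    """
    means = _arm_means_or_raise(data, arm, "fit_quality")
    days = means["day"].to_numpy(dtype=float)
    observed = means["volume_mm3"].to_numpy(dtype=float)
    if isinstance(model_volumes, TrajectorySeries):
        predicted = model_volumes.volume_at(days)
    else:
        predicted = np.asarray(model_volumes, dtype=float)
        if predicted.shape != observed.shape:
            raise InputDomainError("model and observed vectors must align")
    if len(observed) < 3:
        raise CalibrationError("fit_quality", "need >= 3 matched (model, observed) pairs")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise InputDomainError("Pearson R undefined: zero variance in a vector")
    r, p = stats.pearsonr(predicted, observed)
    return float(r), float(p)
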