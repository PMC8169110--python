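"""statsmodels-style facade: TumorGrowthModel.fit() -> SequentialFitResults.

Example
-------
>>> from tumorpkpd import TumorGrowthModel, default_parameters, synthetic
>>> cohort = synthetic.generate_cohort(default_parameters(), seed=7)
>>> pk = synthetic.generate_gcv_pk_samples(12.0, 3.0, 0.008, seed=7)
>>> res = TumorGrowthModel(cohort, gcv_pk=pk).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, io
from .calibration import DEFAULT_SEED, FitResult
from .dynamics import TrajectorySeries
from .errors import CalibrationError
from .params import GCV_DOSE_AMOUNT, ModelParameters, default_parameters
from .trial import (
    TrialSettings,
    arm_trajectory,
    compare_bolus_vs_infusion,
    kd_sensitivity,
    simulate_gene_therapy_experiment,
)


class TumorGrowthModel:
    """The tumor-growth / PK model bound to a cohort of measurements.

    Parameters
    ----------
    cohort
        Long-format measurements with columns ``arm, subject_id, day,
        volume_mm3``. Arms beyond those required by the requested stages may
        be absent.
    gcv_pk
        Optional GCV plasma-concentration series (columns ``day,
        concentration``) after a single ip dose; when omitted, the GCV PK
        stage is skipped and ``base_params`` supplies (ka_gcv, kex_gcv).
    base_params
        Source of fixed quantities (carrying capacity K) and of defaults for
        any stage that is skipped. Defaults to the packaged reference set.
    gcv_c0ip
        Nominal peritoneal concentration of one GCV dose (mg/mm^3).
    weights
        ``"ols"`` (default) or ``"inverse_variance"`` (1/SD^2 per day).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        gcv_pk: pd.DataFrame | None = None,
        base_params: ModelParameters | None = None,
        gcv_c0ip: float = GCV_DOSE_AMOUNT,
        weights: str = "ols",
    ):
        self.cohort = io.validate_cohort(cohort)
        self.gcv_pk = gcv_pk
        self.base_params = base_params if base_params is not None else default_parameters()
        self.gcv_c0ip = gcv_c0ip
        self.weights = weights

    @classmethod
    def from_csv(
        cls,
        cohort_csv: str | Path,
        pk_csv: str | Path | None = None,
        **kwargs,
    ) -> "TumorGrowthModel":
        cohort = io.read_cohort_csv(cohort_csv)
        pk = io.read_pk_csv(pk_csv) if pk_csv is not None else None
        return cls(cohort, gcv_pk=pk, **kwargs)

    def fit(self, seed: int = DEFAULT_SEED, n_starts: int = 8) -> "SequentialFitResults":
        """Run the full sequential calibration in study order.

        Stages whose arms are absent from the cohort fall back to
        ``base_params`` and are recorded as skipped; the mandatory first
        stage (growth rate from the control arm) must be runnable.
        """
        arms_present = set(self.cohort["arm"].unique())
        if "control_gcv_only" not in arms_present:
            raise CalibrationError(
                "fit_growth_rate",
                "control arm 'control_gcv_only' is required before any later stage",
            )
        stages: dict[str, FitResult] = {}
        K = self.base_params.K

        sigma, res_sigma = calibration.fit_growth_rate(
            self.cohort, K=K, weights=self.weights
        )
        stages[res_sigma.stage] = res_sigma

        V0 = calibration.extrapolate_initial_volume(
            sigma,
            K=K,
            anchor=(res_sigma.params["anchor_day"], res_sigma.params["anchor_volume"]),
        )

        if self.gcv_pk is not None:
            ka, kex_gcv, res_pk = calibration.fit_gcv_pk(self.gcv_pk, self.gcv_c0ip)
            stages[res_pk.stage] = res_pk
        else:
            ka, kex_gcv = self.base_params.ka_gcv, self.base_params.kex_gcv

        if "fd_aavp_gcv" in arms_present:
            lam, res_lam = calibration.fit_gcv_death(
                self.cohort, sigma, V0, (ka, kex_gcv), self.base_params,
                weights=self.weights,
            )
            stages[res_lam.stage] = res_lam
        else:
            lam = self.base_params.lam

        if "csstresac_aavp_gcv" in arms_present:
            pep, res_pep = calibration.fit_peptide_params(
                self.cohort, sigma, V0, lam, (ka, kex_gcv), self.base_params,
                n_starts=n_starts, seed=seed, weights=self.weights,
            )
            stages[res_pep.stage] = res_pep
        else:
            pep = {
                "D_pep": self.base_params.D_pep,
                "Kd": self.base_params.Kd,
                "kex_pep": self.base_params.kex_pep,
            }

        if "soluble_csstresac" in arms_present:
            kex_sol, res_sol = calibration.refit_soluble_excretion(
                self.cohort, sigma, V0, pep["D_pep"], pep["Kd"], self.base_params,
                weights=self.weights,
            )
            stages[res_sol.stage] = res_sol
        else:
            kex_sol = self.base_params.kex_pep_sol

        params = self.base_params.replace(
            sigma=sigma,
            V0=V0,
            lam=lam,
            D_pep=pep["D_pep"],
            Kd=pep["Kd"],
            kex_pep=pep["kex_pep"],
            kex_pep_sol=kex_sol,
            ka_gcv=ka,
            kex_gcv=kex_gcv,
        )

        r = p = None
        if "csstresac_aavp_gcv" in arms_present:
            traj = arm_trajectory(params, "csstresac_aavp_gcv")
            r, p = calibration.fit_quality(traj, self.cohort)

        return SequentialFitResults(
            model=self, params=params, stages=stages, pearson_r=r, pearson_p=p
        )


@dataclass
class SequentialFitResults:
    """Estimates, per-stage diagnostics and simulators from a fitted model."""

    model: TumorGrowthModel
    params: ModelParameters
    stages: dict[str, FitResult]
    pearson_r: float | None = None
    pearson_p: float | None = None

    # -- diagnostics -------------------------------------------------------

    @property
    def rss(self) -> float:
        """Total residual sum of squares across fitted stages."""
        return float(sum(s.rss for s in self.stages.values()))

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.stages.values())

    def predict(self, arm: str, days: np.ndarray | list[float]) -> np.ndarray:
        """Model-mean tumor volumes for an arm at the given days."""
        days = np.asarray(days, dtype=float)
        traj = arm_trajectory(self.params, arm, t_span=(0.0, float(days.max())))
        return traj.volume_at(days)

    def residuals(self, arm: str) -> pd.DataFrame:
        means = io.arm_means(self.model.cohort, arm)
        pred = self.predict(arm, means["day"].to_numpy())
        return means.assign(
            predicted_mm3=pred, residual_mm3=means["volume_mm3"].to_numpy() - pred
        )

    # -- simulation --------------------------------------------------------

    def simulate_experiment(self, **kwargs) -> dict[str, TrajectorySeries]:
        return simulate_gene_therapy_experiment(self.params, **kwargs)

    def trial_settings(self, mode: str, **kwargs) -> TrialSettings:
        return TrialSettings(params=self.params, mode=mode, **kwargs)

    def compare_bolus_vs_infusion(self, mu: float = 0.75, horizon: float = 60.0) -> float:
        return compare_bolus_vs_infusion(
            self.trial_settings("bolus", horizon=horizon),
            self.trial_settings("infusion", mu=mu, horizon=horizon),
        )

    def kd_sensitivity(self, perturbation: float = 0.20, **kwargs) -> dict[str, float]:
        return kd_sensitivity(self.trial_settings("infusion", **kwargs), perturbation)

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "stages": {k: v.to_dict() for k, v in self.stages.items()},
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "rss": self.rss,
            "converged": self.converged,
        }

    def summary(self) -> str:
        """Human-readable per-stage summary table."""
        lines = [
            "Sequential tumor-growth model calibration",
            "=" * 57,
            f"{'parameter':<14}{'estimate':>14}  {'stage':<27}",
            "-" * 57,
        ]
        origin = {
            "sigma": "fit_growth_rate",
            "V0": "extrapolate_initial_volume",
            "ka_gcv": "fit_gcv_pk",
            "kex_gcv": "fit_gcv_pk",
            "lam": "fit_gcv_death",
            "D_pep": "fit_peptide_params",
            "Kd": "fit_peptide_params",
            "kex_pep": "fit_peptide_params",
            "kex_pep_sol": "refit_soluble_excretion",
            "K": "fixed (literature)",
        }
        fitted_stages = set(self.stages)
        if "fit_growth_rate" in fitted_stages:
            # V0 is derived by closed-form extrapolation from that stage's anchor
            fitted_stages.add("extrapolate_initial_volume")
        for name, value in self.params.to_dict().items():
            stage = origin.get(name, "fixed")
            tag = stage if stage in fitted_stages or stage.startswith("fixed") else f"{stage} (default)"
            lines.append(f"{name:<14}{value:>14.6g}  {tag:<27}")
        lines.append("-" * 57)
        if self.pearson_r is not None:
            lines.append(
                f"Pearson R (treated arm) = {self.pearson_r:.4f} "
                f"(p = {self.pearson_p:.3g})"
            )
        lines.append(f"total RSS = {self.rss:.6g}   converged = {self.converged}")
        for stage, res in self.stages.items():
            if res.message:
                lines.append(f"note [{stage}]: {res.message}")
        return "\n".join(lines)
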