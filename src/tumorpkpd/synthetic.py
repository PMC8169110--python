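"""Synthetic cohorts and PK samples with the structure the calibration assumes.

The mouse tumor-volume data exist only as figures, so this module generates
stand-ins with the experiment's design: n = 10 subjects per arm, caliper
measurements starting one week after treatment initiation and every other day
afterwards (days 15, 17, 19, 21 on the implantation clock), volumes following
the model's arm dynamics under the study dose schedules, perturbed by
multiplicative lognormal observation noise (CV 10 % by default — caliper
error scales with tumor size and keeps volumes positive).

GCV plasma kinetics after ip dosing are likewise emulated as noisy samples of
the Bateman curve, standing in for literature-digitized concentration data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError, InputDomainError
from .params import ModelParameters
from .pk import ip_bateman_concentration
from .trial import arm_trajectory

__all__ = [
    "NoiseModel",
    "generate_cohort",
    "generate_gcv_pk_samples",
    "DEFAULT_TUMOR_DAYS",
    "DEFAULT_PK_TIMES",
]

#: Caliper measurement days (every other day from one week post treatment
#: initiation, implantation clock).
DEFAULT_TUMOR_DAYS = (15.0, 17.0, 19.0, 21.0)

#: Eight log-spaced PK sampling times over 12 h (days).
DEFAULT_PK_TIMES = tuple(np.geomspace(0.01, 0.5, 8))

DEFAULT_SEED = 20210601


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise specification.

    kind
        ``"none"``, ``"multiplicative_lognormal"`` (scale = coefficient of
        variation; mean-one noise factor) or ``"additive_gaussian"``
        (scale = SD in measurement units; negative draws clipped to 0).
    """

    kind: str = "multiplicative_lognormal"
    scale: float = 0.10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_lognormal", "additive_gaussian"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise InputDomainError("noise scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.scale == 0:
            return values.copy()
        if self.kind == "multiplicative_lognormal":
            # lognormal with unit mean: E[exp(N(-s^2/2, s^2))] = 1
            s = np.sqrt(np.log1p(self.scale**2))
            factors = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=values.shape)
            return values * factors
        return np.clip(values + rng.normal(0.0, self.scale, size=values.shape), 0.0, None)


def generate_cohort(
    true_params: ModelParameters,
    arms: tuple[str, ...] = io.ARMS,
    n_subjects: int = 10,
    days: tuple[float, ...] = DEFAULT_TUMOR_DAYS,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject tumor volumes for the requested arms.

    Each subject's volumes are the arm's deterministic model trajectory at
    the measurement days, perturbed independently per (subject, day) by the
    noise model. Same seed, same output — byte-identical CSVs.
    """
    if n_subjects < 1:
        raise InputDomainError("n_subjects must be >= 1")
    if len(days) == 0:
        raise InputDomainError("day grid must be non-empty")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    days_arr = np.asarray(sorted(days), dtype=float)
    records = []
    for arm in arms:
        traj = arm_trajectory(
            true_params, arm, t_span=(0.0, float(days_arr[-1])), t_eval=None
        )
        truth = traj.volume_at(days_arr)
        for subject in range(1, n_subjects + 1):
            observed = noise.apply(truth, rng)
            for day, vol in zip(days_arr, observed):
                records.append(
                    {
                        "arm": arm,
                        "subject_id": f"{arm}_{subject:02d}",
                        "day": day,
                        "volume_mm3": vol,
                    }
                )
    return io.validate_cohort(pd.DataFrame.from_records(records))


def generate_gcv_pk_samples(
    ka: float,
    kex: float,
    C0IP: float,
    sample_times: tuple[float, ...] = DEFAULT_PK_TIMES,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy Bateman-curve samples of GCV plasma concentration after one ip dose."""
    if ka <= 0 or kex <= 0:
        raise InputDomainError("ka and kex must be > 0")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    t = np.asarray(sorted(sample_times), dtype=float)
    conc = ip_bateman_concentration(t, C0IP, ka, kex)
    return pd.DataFrame({"day": t, "concentration": noise.apply(conc, rng)})
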