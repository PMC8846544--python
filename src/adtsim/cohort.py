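"""Synthetic longitudinal PSA cohorts and depot-PK fixture profiles.

The generator emulates the structure of a pre-treatment ("watchful
waiting") registry cohort: 19 patients, 6–22 PSA measurements each over
spans of roughly one to fifteen years, PSA from below detection to the
10^3 ng/ml range, irregular sampling.  Each patient draws individual
growth-law parameters lognormally around the population values (log-scale
random effects guarantee positive rates), a baseline PSA log-uniform in
the design range, and observation noise additive on log(P/P_R).
Observations falling below the detection level P_R are floored at P_R
and flagged as censored.

A single global seed feeds a splittable per-patient stream
(``numpy.random.SeedSequence.spawn``), so cohorts are reproducible
patient-by-patient regardless of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import CLOSED_FORM_LAWS, GrowthLawSpec, _predict_log_ratio_ode, predict_log_ratio
from .pk import DiffusionPKParams, DoseSchedule, integrate_diffusion_pk

__all__ = [
    "CohortDesign",
    "PopulationSpec",
    "Cohort",
    "default_population",
    "generate_cohort",
    "generate_pk_profiles",
]

_SAMPLING = ("uniform_random", "evenly_spaced")


@dataclass
class CohortDesign:
    """Cohort shape: patient count, per-patient point counts/timespans,
    baseline PSA range, and the sampling pattern of visit times."""

    n_patients: int = 19
    points_per_patient_range: tuple = (6, 22)
    timespan_range_days: tuple = (388.0, 5724.0)
    baseline_psa_range: tuple = (0.5, 20.0)
    sampling: str = "uniform_random"

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.points_per_patient_range
        if not (2 <= lo <= hi):
            raise ValueError("points per patient must satisfy 2 <= min <= max")
        lo, hi = self.timespan_range_days
        if not (0 < lo <= hi):
            raise ValueError("timespan range must be positive with min <= max")
        lo, hi = self.baseline_psa_range
        if not (0 <= lo <= hi) or hi <= 0:
            raise ValueError("baseline PSA range must be nonnegative with min <= max")
        if self.sampling not in _SAMPLING:
            raise ValueError(f"sampling must be one of {_SAMPLING}")


@dataclass
class PopulationSpec:
    """Population-level data-generating model.

    ``law.params`` are the fixed effects (population-typical values);
    ``random_effect_sd`` maps parameter names to log-scale standard
    deviations (individual parameters are lognormal around the fixed
    effect); ``residual_sd`` is the SD of additive noise on log(P/P_R).
    """

    law: GrowthLawSpec
    random_effect_sd: dict = field(default_factory=lambda: {"a": 0.4})
    residual_sd: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")
        for k, v in self.random_effect_sd.items():
            if v < 0:
                raise ValueError(f"random-effect SD for {k!r} must be nonnegative")
            if k not in self.law.params:
                raise ValueError(f"{k!r} is not a parameter of the {self.law.name} law")


def default_population(seed: int = 0) -> PopulationSpec:
    """Log-power population with defaults matching the emulated registry:
    a = 5e-4/day, b = 1, gamma = 0.5, P_R = 1 ng/ml, random effect SD 0.4
    on log a, residual SD 0.55 on the log scale."""
    law = GrowthLawSpec("log_power", {"a": 5e-4, "b": 1.0, "gamma": 0.5}, p_r=1.0)
    return PopulationSpec(law=law, seed=seed)


@dataclass
class Cohort:
    """Longitudinal PSA observations plus (for synthetic cohorts) the
    per-patient true parameters used to generate them."""

    data: pd.DataFrame  # patient_id, time_days, psa_ng_ml, censored
    p_r: float = 1.0
    true_params: pd.DataFrame | None = None

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def patients(self):
        """Iterate (patient_id, sub-DataFrame sorted by time)."""
        for pid, g in self.data.groupby("patient_id", sort=False):
            yield pid, g.sort_values("time_days")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, p_r: float = 1.0) -> "Cohort":
        df = pd.read_csv(path)
        required = {"patient_id", "time_days", "psa_ng_ml", "censored"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort file missing columns {sorted(missing)}")
        return cls(data=df, p_r=p_r)


def generate_cohort(design: CohortDesign, pop: PopulationSpec) -> Cohort:
    """Draw a synthetic cohort under the given design and population model.

    Per patient: point count uniform over the design range; visit times
    at t = 0 and the timespan end plus uniform-random (or evenly spaced)
    interior points; baseline PSA log-uniform in the design range;
    individual parameters lognormal around the fixed effects; log-scale
    trajectories from the growth law plus N(0, residual_sd) noise.
    With zero random effects and zero residual SD the output equals the
    deterministic model prediction.
    """
    law = pop.law
    p_r = law.p_r
    ss = np.random.SeedSequence(pop.seed)
    children = ss.spawn(design.n_patients)
    rows = []
    true_rows = []
    lo_n, hi_n = design.points_per_patient_range
    lo_T, hi_T = design.timespan_range_days
    lo_P, hi_P = design.baseline_psa_range
    lo_P = max(lo_P, 1e-6)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_pts = int(rng.integers(lo_n, hi_n + 1))
        span = float(rng.uniform(lo_T, hi_T))
        P0 = float(np.exp(rng.uniform(math.log(lo_P), math.log(hi_P))))
        if design.sampling == "evenly_spaced":
            times = np.linspace(0.0, span, n_pts)
        else:
            inner = np.sort(rng.uniform(0.0, span, size=n_pts - 2))
            times = np.concatenate(([0.0], inner, [span]))
        params = dict(law.params)
        for name, sd in pop.random_effect_sd.items():
            if sd > 0:
                params[name] = params[name] * float(np.exp(sd * rng.standard_normal()))
        law_i = replace(law, params=params)
        y0 = math.log(P0 / p_r)
        if law.name in CLOSED_FORM_LAWS:
            y_true = predict_log_ratio(law_i, y0, times)
        else:
            y_true = _predict_log_ratio_ode(law_i, y0, times)
        y_obs = y_true + (
            pop.residual_sd * rng.standard_normal(n_pts) if pop.residual_sd > 0 else 0.0
        )
        psa = p_r * np.exp(y_obs)
        censored = psa < p_r
        psa = np.where(censored, p_r, psa)
        pid = f"P{i + 1:03d}"
        for t, v, c in zip(times, psa, censored):
            rows.append((pid, float(t), float(v), bool(c)))
        true_rows.append({"patient_id": pid, "P0": P0, "timespan": span, **params})
    data = pd.DataFrame(rows, columns=["patient_id", "time_days", "psa_ng_ml", "censored"])
    return Cohort(data=data, p_r=p_r, true_params=pd.DataFrame(true_rows))


def generate_pk_profiles(
    schedules,
    params: DiffusionPKParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_grid=None,
    points_per_interval: int = 60,
) -> pd.DataFrame:
    """Smooth depot concentration curves plus optional multiplicative noise.

    One curve per schedule from :func:`adtsim.pk.integrate_diffusion_pk`;
    noise is lognormal-multiplicative with log-scale SD ``noise_sd``
    (zero noise returns the deterministic curve exactly).  Returns a
    table (schedule_id, time_days, concentration).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if isinstance(schedules, DoseSchedule):
        schedules = [schedules]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(schedules))
    frames = []
    for sched, child in zip(schedules, children):
        rng = np.random.default_rng(child)
        if t_grid is None:
            t_end = sched.doses[-1][0] + (
                sched.doses[1][0] - sched.doses[0][0] if len(sched.doses) > 1 else 28.0
            )
            n = points_per_interval * max(len(sched.doses), 1)
            grid = np.linspace(0.0, t_end, n)
        else:
            grid = np.asarray(t_grid, dtype=float)
        traj = integrate_diffusion_pk(params, sched, grid)
        conc = traj.concentration
        if noise_sd > 0:
            conc = conc * np.exp(noise_sd * rng.standard_normal(conc.shape))
        frames.append(
            pd.DataFrame(
                {
                    "schedule_id": sched.schedule_id,
                    "time_days": grid,
                    "concentration": conc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
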