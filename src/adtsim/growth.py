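"""Per-capita PSA growth laws and deterministic trajectory integration.

Serum prostate-specific antigen P(t) (ng/ml) is used as the proxy for
tumor burden, evolving as

    dP/dt = P * f(P)        (or f(P, t) for time-modulated laws),

where f is the per-capita growth rate (1/day).  The implemented family:

========================  ==================================================
name                      f(P)
========================  ==================================================
exponential               a
gompertz                  -a ln(P/K)
logistic                  a (1 - P/K)
generalized_logistic      a (1 - (P/K)^gamma)     (Greenspan preset g=2/3)
log_power                 a                        for P <= P_R
                          a (1 + b ln(P/P_R))^g    for P >  P_R, 0 < g < 1
time_modulated            a (1 + lam*t) (P/P_R)^gamma
modulated_exponent        a (P/P_R)^k(t),  dk/dt = lam,  k(0) = k0
========================  ==================================================

``log_power`` is super-exponential above the PSA detection level P_R and
reverts to plain exponential growth below it, which makes f continuous
and defined for all P >= 0 (the unextended formula has a pole at
P_c = P_R exp(-1/b), strictly below P_R).  ``modulated_exponent`` is
non-autonomous and is integrated as the two-state system (P, k).

Integration is carried out in the log variable y = ln(P/P_R), in which
every law has a smooth right-hand side; several laws additionally admit
closed-form solutions in y (see :func:`predict_log_ratio`), which the
population fitter relies on for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LAW_NAMES",
    "GrowthLawSpec",
    "PsaTrajectory",
    "BlowUpError",
    "per_capita_rate",
    "integrate_growth",
    "log_psa_prediction",
    "predict_log_ratio",
]

LAW_NAMES = (
    "exponential",
    "gompertz",
    "logistic",
    "generalized_logistic",
    "log_power",
    "time_modulated",
    "modulated_exponent",
)

# Parameters each law requires (P_R is carried separately on the spec).
_REQUIRED = {
    "exponential": ("a",),
    "gompertz": ("a", "K"),
    "logistic": ("a", "K"),
    "generalized_logistic": ("a", "K", "gamma"),
    "log_power": ("a", "b", "gamma"),
    "time_modulated": ("a", "lam", "gamma"),
    "modulated_exponent": ("a", "lam", "k0"),
}

#: Laws with a closed-form solution for y(t) = ln(P(t)/P_R).
CLOSED_FORM_LAWS = frozenset(
    {
        "exponential",
        "gompertz",
        "logistic",
        "generalized_logistic",
        "log_power",
        "time_modulated",
    }
)


class BlowUpError(RuntimeError):
    """Raised when a super-exponential trajectory exceeds the PSA cap.

    Attributes
    ----------
    bracket : tuple of float
        (last time solved below the cap, time at which the cap was hit).
    """

    def __init__(self, bracket):
        self.bracket = tuple(bracket)
        super().__init__(
            f"PSA trajectory exceeded the cap; blow-up bracketed in "
            f"t = [{self.bracket[0]:.6g}, {self.bracket[1]:.6g}] days"
        )


@dataclass
class GrowthLawSpec:
    """A named per-capita growth law together with its parameter vector.

    Parameters
    ----------
    name : str
        One of :data:`LAW_NAMES`.
    params : dict
        Law parameters (units: ``a`` 1/day, ``b`` and ``gamma``
        dimensionless, ``K`` ng/ml, ``lam`` 1/day, ``k0`` dimensionless).
    p_r : float
        PSA detection level P_R (ng/ml).  Fixed, never fitted.
    """

    name: str
    params: dict = field(default_factory=dict)
    p_r: float = 1.0

    def __post_init__(self):
        if self.name not in LAW_NAMES:
            raise ValueError(f"unknown growth law {self.name!r}")
        missing = [k for k in _REQUIRED[self.name] if k not in self.params]
        if missing:
            raise ValueError(f"{self.name} law missing parameters {missing}")
        p = self.params
        if not self.p_r > 0:
            raise ValueError("P_R must be positive")
        if not p["a"] > 0:
            raise ValueError("a must be positive")
        if self.name == "log_power":
            if not p["b"] > 0:
                raise ValueError("log_power requires b > 0")
            if not 0 < p["gamma"] < 1:
                raise ValueError("log_power requires gamma in (0, 1)")
        if "K" in _REQUIRED[self.name] and not p["K"] > 0:
            raise ValueError("K must be positive")

    @classmethod
    def greenspan(cls, a: float, K: float, p_r: float = 1.0) -> "GrowthLawSpec":
        """Generalized logistic with the Greenspan exponent gamma = 2/3."""
        return cls("generalized_logistic", {"a": a, "K": K, "gamma": 2.0 / 3.0}, p_r)

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params), "p_r": self.p_r}

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthLawSpec":
        return cls(d["name"], dict(d["params"]), float(d.get("p_r", 1.0)))


@dataclass
class PsaTrajectory:
    """A PSA time course: strictly increasing times (days), values (ng/ml)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("PSA values must be positive")

    def log_ratio(self, p_r: float = 1.0) -> np.ndarray:
        return np.log(self.values / p_r)


def per_capita_rate(P, law: GrowthLawSpec, t=0.0):
    """Per-capita growth rate f(P) (or f(P, t)), vectorized over P.

    Gompertz returns +inf at P = 0 (the limit of -a ln(P/K)); the product
    P*f(P) still tends to 0 there, so trajectories remain well defined.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("PSA must be nonnegative")
    p = law.params
    a = p["a"]
    name = law.name
    if name == "exponential":
        out = np.full_like(P, a)
    elif name == "gompertz":
        with np.errstate(divide="ignore"):
            out = np.where(P > 0, -a * np.log(P / p["K"]), np.inf)
    elif name == "logistic":
        out = a * (1.0 - P / p["K"])
    elif name == "generalized_logistic":
        out = a * (1.0 - (P / p["K"]) ** p["gamma"])
    elif name == "log_power":
        out = np.full_like(P, a)
        above = P > law.p_r
        if np.any(above):
            out[above] = a * (1.0 + p["b"] * np.log(P[above] / law.p_r)) ** p["gamma"]
    elif name == "time_modulated":
        out = a * (1.0 + p["lam"] * t) * (P / law.p_r) ** p["gamma"]
    elif name == "modulated_exponent":
        k = p["k0"] + p["lam"] * t
        out = a * (P / law.p_r) ** k
    else:  # pragma: no cover
        raise ValueError(name)
    return out if out.ndim else float(out)


def _log_rate(y: float, law: GrowthLawSpec, t: float, k: float | None = None) -> float:
    """dy/dt for y = ln(P/P_R)."""
    p = law.params
    a = p["a"]
    name = law.name
    if name == "exponential":
        return a
    if name == "gompertz":
        kappa = math.log(p["K"] / law.p_r)
        return a * (kappa - y)
    if name == "logistic":
        kappa = math.log(p["K"] / law.p_r)
        return a * (1.0 - math.exp(y - kappa))
    if name == "generalized_logistic":
        kappa = math.log(p["K"] / law.p_r)
        return a * (1.0 - math.exp(p["gamma"] * (y - kappa)))
    if name == "log_power":
        if y <= 0:
            return a
        return a * (1.0 + p["b"] * y) ** p["gamma"]
    if name == "time_modulated":
        return a * (1.0 + p["lam"] * t) * math.exp(p["gamma"] * y)
    if name == "modulated_exponent":
        return a * math.exp((p["k0"] + p["lam"] * t if k is None else k) * y)
    raise ValueError(name)  # pragma: no cover


def integrate_growth(
    P0: float,
    law: GrowthLawSpec,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    psa_cap: float = 1e6,
) -> PsaTrajectory:
    """Numerically solve dP/dt = P f(P) on the given time grid.

    Integration runs in y = ln(P/P_R).  ``modulated_exponent``
    co-integrates the exponent state k (dk/dt = lam).  Super-exponential
    blow-up (P exceeding ``psa_cap``) raises :class:`BlowUpError` with a
    bracket on the blow-up time.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if not P0 > 0:
        raise ValueError("P0 must be positive")
    y_cap = math.log(psa_cap / law.p_r)
    two_state = law.name == "modulated_exponent"

    if two_state:
        s0 = [math.log(P0 / law.p_r), law.params["k0"]]

        def rhs(ti, s):
            return [_log_rate(s[0], law, ti, k=s[1]), law.params["lam"]]

    else:
        s0 = [math.log(P0 / law.p_r)]

        def rhs(ti, s):
            return [_log_rate(s[0], law, ti)]

    def hit_cap(ti, s):
        return s[0] - y_cap

    hit_cap.terminal = True
    hit_cap.direction = 1

    sol = solve_ivp(
        rhs, (t[0], t[-1]), s0, t_eval=t, rtol=rtol, atol=atol,
        method="LSODA", events=hit_cap,
    )
    if sol.t_events[0].size:
        t_hit = float(sol.t_events[0][0])
        below = sol.t[sol.t < t_hit]
        t_lo = float(below[-1]) if below.size else float(t[0])
        raise BlowUpError((t_lo, t_hit))
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"growth integration failed: {sol.message}")
    return PsaTrajectory(sol.t, law.p_r * np.exp(sol.y[0]))


def predict_log_ratio(law: GrowthLawSpec, y0, times):
    """Closed-form y(t) = ln(P(t)/P_R) with y(0) = y0, vectorized.

    Supports elementwise-varying parameters and initial conditions: every
    entry of ``law.params`` and ``y0`` may be a scalar or an array
    broadcastable against ``times``.  Laws without a closed form
    (``modulated_exponent``) fall back to numerical integration and then
    require scalar inputs.

    ``time_modulated`` blows up in finite time; beyond the blow-up the
    prediction is +inf.
    """
    if law.name in CLOSED_FORM_LAWS:
        return closed_form_log_ratio(law.name, law.params, law.p_r, y0, times)
    # no closed form: numerical fallback (scalar y0 / params only)
    return _predict_log_ratio_ode(law, float(y0), np.asarray(times, dtype=float))


def closed_form_log_ratio(name: str, params: dict, p_r: float, y0, times):
    """Validation-free closed-form kernel behind :func:`predict_log_ratio`.

    Accepts array-valued parameters (one value per evaluation point),
    which the population fitter uses for whole-cohort predictions in a
    single vectorized call.
    """
    t = np.asarray(times, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    p = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    a = p["a"]

    if name == "exponential":
        return y0 + a * t

    if name == "gompertz":
        kappa = np.log(p["K"] / p_r)
        return kappa + (y0 - kappa) * np.exp(-a * t)

    if name == "logistic":
        kappa = np.log(p["K"] / p_r)
        u0 = np.exp(y0 - kappa)
        u = u0 / (u0 + (1.0 - u0) * np.exp(-a * t))
        return kappa + np.log(u)

    if name == "generalized_logistic":
        g = p["gamma"]
        kappa = np.log(p["K"] / p_r)
        v0 = np.exp(g * (y0 - kappa))
        v = v0 / (v0 + (1.0 - v0) * np.exp(-a * g * t))
        return kappa + np.log(v) / g

    if name == "log_power":
        b, g = p["b"], p["gamma"]
        # Exponential branch below detection; the log-power branch starts
        # once y reaches 0 (continuity of the extended law).
        t_cross = np.where(y0 < 0, -y0 / a, 0.0)
        y_lin = y0 + a * t
        w0 = np.where(y0 < 0, 1.0, (1.0 + b * np.maximum(y0, 0.0)) ** (1.0 - g))
        dt = np.maximum(t - t_cross, 0.0)
        w = w0 + a * b * (1.0 - g) * dt
        y_pow = (w ** (1.0 / (1.0 - g)) - 1.0) / b
        return np.where(t < t_cross, y_lin, y_pow)

    if name == "time_modulated":
        g, lam = p["gamma"], p["lam"]
        E = np.exp(-g * y0) - g * a * (t + lam * t**2 / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = -np.log(E) / g
        return np.where(E > 0, y, np.inf)

    # no closed form: numerical fallback (scalar y0 / params only)
    return _predict_log_ratio_ode(law, float(y0), t)


def _predict_log_ratio_ode(law: GrowthLawSpec, y0: float, t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    order = np.argsort(t)
    ts = t[order]
    grid = ts if ts[0] == 0.0 else np.concatenate(([0.0], ts))
    traj = integrate_growth(law.p_r * math.exp(y0), law, grid)
    y = np.log(traj.values / law.p_r)
    if ts[0] != 0.0:
        y = y[1:]
    out = np.empty_like(y)
    out[order] = y
    return out


def log_psa_prediction(law: GrowthLawSpec, P0: float, t) -> np.ndarray:
    """ln(P(t)/P_R) for the trajectory started at P0 — the quantity the
    population fitter works with.  Uses closed forms where available."""
    y0 = math.log(P0 / law.p_r)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if law.name in CLOSED_FORM_LAWS:
        out = predict_log_ratio(law, y0, t_arr)
    else:
        out = _predict_log_ratio_ode(law, y0, t_arr)
    return out if np.ndim(t) else float(out[0])
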