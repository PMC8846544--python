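"""Coupled PSA–hormone treatment model, acquired resistance, and the
threshold theory of treatment failure.

Without resistance the treated system is

    dP/dt = P f(P) + dP_coef (z - z0_bar) P,
    dx/dt = h1(z) - d1 x,
    dz/dt = h3(x, L) - d3 z,

where z0_bar is the untreated testosterone steady state, so PSA growth
is boosted (suppressed) when testosterone sits above (below) its
untreated level.  Two acquired-resistance mechanisms extend it:

    dr_i/dt = beta_i L (1 - r_i / l_i),   r_i(0) = 0,

with r1 (testosterone-independent PSA regrowth, g1(r1) = a1 r1 added to
the PSA drive) and r2 (drug-tolerance of TES production: the drug level
seen by h3 becomes g2(r2) = L (a2 + e^{r2}) / ((a2+1) e^{r2}), which
decreases from g2(0) = L towards L/(a2+1)).  Each r_i stays in [0, l_i).

Asymptotically (constant L) the PSA equation decouples to

    dP/dt = P f(P) - dP_coef (z0_bar - z_L) P,

which for the log-power growth law has the unstable threshold

    P_bar = P_R exp( ((dP_coef (z0_bar - z_L) / a)^{1/gamma} - 1) / b )

whenever a < dP_coef (z0_bar - z_L): PSA below P_bar decays to cure,
above it escapes to infinity.  Since z_inf = 0, the critical growth rate
a_tilde = dP_coef * z0_bar separates patients curable by some dose from
those uncurable at any dose.  With the first resistance mechanism
saturated (r1 -> l1) the deficit shrinks to z0_bar - z_L - a1 l1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .growth import GrowthLawSpec, _log_rate
from .hormones import HormoneParams, steady_state_two_with_drug

__all__ = [
    "ResistanceParams",
    "FullModelParams",
    "RegimeReport",
    "g1",
    "g2",
    "critical_growth_rate",
    "psa_threshold",
    "classify_regime",
    "resistance_closed_form",
    "integrate_full_model",
    "reduced_resistance_system",
    "reduced_resistance_steady_state",
    "simulate_asymptotic_psa",
    "threshold_by_bisection",
    "detect_biochemical_failure",
]


@dataclass
class ResistanceParams:
    """Acquired-resistance rates and saturation levels (all nonnegative).

    beta1/beta2 are induction rates (1/(day*drug-unit)), l1/l2 the
    saturation levels of r1/r2, a1 the slope of g1, a2 the shape of g2.
    """

    beta1: float = 0.0
    beta2: float = 0.0
    l1: float = 1.0
    l2: float = 1.0
    a1: float = 0.0
    a2: float = 1.0

    def __post_init__(self):
        for name in ("beta1", "beta2", "l1", "l2", "a1", "a2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("saturation levels l1, l2 must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("beta1", "beta2", "l1", "l2", "a1", "a2")}

    @classmethod
    def from_dict(cls, d: dict) -> "ResistanceParams":
        return cls(**{k: float(v) for k, v in d.items()})


def g1(r, a1: float):
    """Testosterone-independent PSA drive of resistance 1: a1 * r."""
    return a1 * np.asarray(r, dtype=float)


def g2(r, L: float, a2: float):
    """Effective drug level under resistance 2:
    L (a2 + e^r)/((a2+1) e^r); g2(0) = L, decreasing to L/(a2+1)."""
    r = np.asarray(r, dtype=float)
    return L * (a2 + np.exp(r)) / ((a2 + 1.0) * np.exp(r))


@dataclass
class FullModelParams:
    """Everything the treated-patient simulator needs.

    ``z0_bar`` is always derived from the hormone submodel at L = 0
    (keeping the untreated baseline self-consistent), never free.
    """

    growth: GrowthLawSpec
    dP: float
    hormones: HormoneParams = field(default_factory=HormoneParams)
    resistance: ResistanceParams = field(default_factory=ResistanceParams)

    def __post_init__(self):
        if self.dP < 0:
            raise ValueError("dP must be nonnegative")

    @property
    def z0_bar(self) -> float:
        """Untreated testosterone steady state."""
        return steady_state_two_with_drug(self.hormones, 0.0)[1]

    @property
    def x0_bar(self) -> float:
        return steady_state_two_with_drug(self.hormones, 0.0)[0]


@dataclass
class RegimeReport:
    """Outcome of the asymptotic threshold analysis at constant L."""

    regime: str  # "no_positive_SS_unbounded" | "threshold_exists"
    P_bar: float | None
    a_tilde: float
    effective_condition: str
    predicted_fate: str | None = None


def critical_growth_rate(p: FullModelParams) -> float:
    """a_tilde = dP * z0_bar: growth rates above it are uncurable at any
    dose; dP -> 0 (castrate-resistant limit) sends a_tilde -> 0."""
    return p.dP * p.z0_bar


def _deficit(p: FullModelParams, L: float, saturated_r1: bool, extra_dp_factor: bool) -> float:
    """Effective testosterone deficit A = z0_bar - z_L (- a1 l1 with the
    first resistance mechanism saturated)."""
    A = p.z0_bar - steady_state_two_with_drug(p.hormones, L)[1]
    if saturated_r1:
        shift = p.resistance.a1 * p.resistance.l1
        if extra_dp_factor:
            # alternative typographic reading with an extra dP factor
            shift *= p.dP
        A -= shift
    return A


def psa_threshold(
    p: FullModelParams,
    L: float,
    saturated_r1: bool = False,
    extra_dp_factor: bool = False,
) -> float | None:
    """Unstable PSA threshold P_bar at constant drug level L, or None.

    Exists iff a < dP * A with A the effective testosterone deficit;
    then P_bar = P_R exp(((dP A / a)^{1/gamma} - 1)/b) >= P_R and is
    increasing in L.  Only defined for the log-power growth law.
    """
    if p.growth.name != "log_power":
        raise ValueError("the threshold formula is specific to the log_power law")
    if L < 0:
        raise ValueError("L must be nonnegative")
    a = p.growth.params["a"]
    b = p.growth.params["b"]
    gam = p.growth.params["gamma"]
    A = _deficit(p, L, saturated_r1, extra_dp_factor)
    ratio = p.dP * A / a
    if ratio <= 1.0:
        return None
    return p.growth.p_r * math.exp((ratio ** (1.0 / gam) - 1.0) / b)


def classify_regime(p: FullModelParams, L: float, P0: float | None = None) -> RegimeReport:
    """Compare a with a_tilde and dP(z0_bar - z_L); predict the PSA fate.

    P0 exactly at P_bar is flagged non-generic (unstable equilibrium).
    """
    a = p.growth.params["a"]
    a_tilde = critical_growth_rate(p)
    if a > a_tilde:
        return RegimeReport(
            regime="no_positive_SS_unbounded",
            P_bar=None,
            a_tilde=a_tilde,
            effective_condition="a > a_tilde: unbounded PSA growth at every dose",
            predicted_fate=None if P0 is None else "escape",
        )
    P_bar = psa_threshold(p, L)
    if P_bar is None:
        return RegimeReport(
            regime="no_positive_SS_unbounded",
            P_bar=None,
            a_tilde=a_tilde,
            effective_condition=(
                "a < a_tilde but a > dP (z0_bar - z_L) at this L: dose too small"
            ),
            predicted_fate=None if P0 is None else "escape",
        )
    fate = None
    if P0 is not None:
        if P0 == P_bar:
            fate = "non_generic"
        else:
            fate = "decay" if P0 < P_bar else "escape"
    return RegimeReport(
        regime="threshold_exists",
        P_bar=P_bar,
        a_tilde=a_tilde,
        effective_condition="a < dP (z0_bar - z_L): unstable threshold P_bar exists",
        predicted_fate=fate,
    )


def resistance_closed_form(t, beta: float, l: float, L: float):
    """r(t) = l (1 - exp(-beta L t / l)) under constant L, r(0) = 0;
    bounded in [0, l)."""
    t = np.asarray(t, dtype=float)
    out = l * (1.0 - np.exp(-beta * L * t / l))
    return out if out.ndim else float(out)


def integrate_full_model(
    p: FullModelParams,
    drug,
    P0: float,
    t_grid,
    x0: float | None = None,
    z0: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    psa_cap: float = 1e6,
) -> pd.DataFrame:
    """Integrate the five-state treated-patient model (P, x, z, r1, r2).

    ``drug`` is a constant L or a callable t -> L(t) (e.g. a PK
    trajectory interpolator; the analysis assumes constant L, the
    time-varying mode is a simulator extension in which dr_i/dt uses the
    instantaneous L(t)).  Hormones start at their untreated steady state
    unless x0/z0 are given; r1(0) = r2(0) = 0 always.

    Returns a DataFrame (time, P, x, z, r1, r2, L).  If PSA exceeds
    ``psa_cap`` (clinical escape) the trajectory is truncated there and
    the blow-up bracket is reported in ``df.attrs["blow_up"]``.
    """
    t = np.asarray(t_grid, dtype=float)
    if not P0 > 0:
        raise ValueError("P0 must be positive")
    L_fun = drug if callable(drug) else (lambda _t, _L=float(drug): _L)
    h = p.hormones
    r = p.resistance
    if x0 is None or z0 is None:
        xs, zs = steady_state_two_with_drug(h, 0.0)
        x0 = xs if x0 is None else x0
        z0 = zs if z0 is None else z0
    z0_bar = p.z0_bar
    y_cap = math.log(psa_cap / p.growth.p_r)

    def rhs(ti, s):
        y, x, z, r1, r2 = s
        L = L_fun(ti)
        f = _log_rate(min(y, y_cap + 10.0), p.growth, ti)
        geff = g2(r2, L, r.a2) if L > 0 else 0.0
        return [
            f + p.dP * (z - z0_bar + r.a1 * r1),
            h.p1 / (1.0 + h.b1 * z) - h.d1 * x,
            h.p3 * x / (1.0 + h.b3 * (x + geff)) - h.d3 * z,
            r.beta1 * L * (1.0 - r1 / r.l1),
            r.beta2 * L * (1.0 - r2 / r.l2),
        ]

    def hit_cap(ti, s):
        return s[0] - y_cap

    hit_cap.terminal = True
    hit_cap.direction = 1

    s0 = [math.log(P0 / p.growth.p_r), x0, z0, 0.0, 0.0]
    sol = solve_ivp(
        rhs, (t[0], t[-1]), s0, t_eval=t, rtol=rtol, atol=atol,
        method="LSODA", events=hit_cap,
    )
    if not sol.success and not sol.t_events[0].size:  # pragma: no cover
        raise RuntimeError(f"full-model integration failed: {sol.message}")
    times = sol.t
    L_vals = np.array([L_fun(ti) for ti in times])
    df = pd.DataFrame(
        {
            "time": times,
            "P": p.growth.p_r * np.exp(sol.y[0]),
            "x": sol.y[1],
            "z": sol.y[2],
            "r1": sol.y[3],
            "r2": sol.y[4],
            "L": L_vals,
        }
    )
    if sol.t_events[0].size:
        t_hit = float(sol.t_events[0][0])
        t_lo = float(times[-1]) if times.size else float(t[0])
        df.attrs["blow_up"] = (t_lo, t_hit)
    return df


def reduced_resistance_system(
    p: FullModelParams, L: float, t_grid, x0=None, z0=None, r2_0: float = 0.0,
    rtol: float = 1e-10, atol: float = 1e-12,
) -> pd.DataFrame:
    """The (x, z, r2) subsystem at constant L (beta3 = beta2 * L const).

    Converges to its unique positive steady state with r2_bar = l2.
    """
    t = np.asarray(t_grid, dtype=float)
    h = p.hormones
    r = p.resistance
    beta3 = r.beta2 * L
    if x0 is None or z0 is None:
        xs, zs = steady_state_two_with_drug(h, 0.0)
        x0 = xs if x0 is None else x0
        z0 = zs if z0 is None else z0

    def rhs(ti, s):
        x, z, r2 = s
        return [
            h.p1 / (1.0 + h.b1 * z) - h.d1 * x,
            h.p3 * x / (1.0 + h.b3 * (x + g2(r2, L, r.a2))) - h.d3 * z,
            beta3 * (1.0 - r2 / r.l2),
        ]

    sol = solve_ivp(
        rhs, (t[0], t[-1]), [x0, z0, r2_0], t_eval=t, rtol=rtol, atol=atol,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"reduced-system integration failed: {sol.message}")
    return pd.DataFrame({"time": sol.t, "x": sol.y[0], "z": sol.y[1], "r2": sol.y[2]})


def reduced_resistance_steady_state(p: FullModelParams, L: float) -> tuple:
    """Closed-form steady state (x, z, r2=l2) of the reduced (x, z, r2)
    system: z solves
        (c3 + g2(l2)) z^2 + (q1 + c1 (c3 + g2(l2))) z - q1 q3 = 0
    with q_i = p_i/(b_i d_i), c_i = 1/b_i.
    """
    h = p.hormones
    r = p.resistance
    G = float(g2(r.l2, L, r.a2))
    q1 = h.p1 / (h.b1 * h.d1)
    c1 = 1.0 / h.b1
    q3 = h.p3 / (h.b3 * h.d3)
    c3 = 1.0 / h.b3
    A = c3 + G
    B = q1 + c1 * (c3 + G)
    C = -q1 * q3
    z = (-B + math.sqrt(B * B - 4.0 * A * C)) / (2.0 * A)
    x = q1 / (c1 + z)
    return x, z, r.l2


def simulate_asymptotic_psa(
    p: FullModelParams,
    L: float,
    P0: float,
    horizon: float = 20000.0,
    psa_cap: float = 1e6,
    decay_factor: float = 0.5,
    saturated_r1: bool = False,
) -> str:
    """Fate of the decoupled asymptotic PSA equation
    dP/dt = P f(P) - dP_coef * A * P at constant L.

    Returns "decay" (P dropped below decay_factor * P_R), "escape"
    (P exceeded psa_cap), or "indeterminate" if neither event fires by
    the horizon — the statements being asymptotic, the horizon default
    (20 000 days) is deliberately long.
    """
    A = _deficit(p, L, saturated_r1, False)
    dPA = p.dP * A
    y0 = math.log(P0 / p.growth.p_r)
    y_lo = math.log(decay_factor)
    y_hi = math.log(psa_cap / p.growth.p_r)

    def rhs(ti, s):
        return [_log_rate(s[0], p.growth, ti) - dPA]

    def ev_decay(ti, s):
        return s[0] - y_lo

    def ev_escape(ti, s):
        return s[0] - y_hi

    ev_decay.terminal = True
    ev_escape.terminal = True
    sol = solve_ivp(
        rhs, (0.0, horizon), [y0], rtol=1e-10, atol=1e-12, method="LSODA",
        events=[ev_decay, ev_escape],
    )
    if sol.t_events[0].size:
        return "decay"
    if sol.t_events[1].size:
        return "escape"
    return "indeterminate"


def threshold_by_bisection(
    p: FullModelParams,
    L: float,
    horizon: float = 1e5,
    tol_log: float = 1e-3,
    saturated_r1: bool = False,
) -> float:
    """Locate the unstable PSA separatrix by bisection on the ODE fate.

    Independent of the closed-form threshold: brackets [decaying,
    escaping] initial values and bisects on log PSA to ``tol_log``.
    Indeterminate fates at the horizon are classified by the sign of the
    rate at the endpoint (the scalar autonomous flow is monotone on each
    side of the separatrix).
    """
    A = _deficit(p, L, saturated_r1, False)
    dPA = p.dP * A
    a = p.growth.params["a"]
    if a >= dPA:
        raise ValueError("no positive separatrix: a >= dP * A")

    def fate(y0: float) -> str:
        out = simulate_asymptotic_psa(
            p, L, p.growth.p_r * math.exp(y0), horizon=horizon,
            saturated_r1=saturated_r1,
        )
        if out != "indeterminate":
            return out
        # near the unstable point: classify by instantaneous drift
        rate = _log_rate(y0, p.growth, 0.0) - dPA
        return "escape" if rate > 0 else "decay"

    lo = 1e-3
    if fate(lo) != "decay":  # pragma: no cover
        raise RuntimeError("lower bracket did not decay")
    hi = 1.0
    while fate(hi) != "escape":
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover
            raise RuntimeError("failed to bracket an escaping start")
    while hi - lo > tol_log:
        mid = 0.5 * (lo + hi)
        if fate(mid) == "escape":
            hi = mid
        else:
            lo = mid
    return p.growth.p_r * math.exp(0.5 * (lo + hi))


def detect_biochemical_failure(
    times, psa=None, rise_factor: float = 2.0, nadir_window: float = 0.0
):
    """First time PSA exceeds ``rise_factor`` x its running nadir.

    ``times``/``psa`` may also be given as a single DataFrame with
    columns ``time`` and ``P``.  ``nadir_window`` (days) skips the
    initial interval before failure is assessed (the nadir itself is
    still tracked from t = 0).  Returns the (linearly interpolated)
    failure time, or None for monotone-declining PSA.
    """
    if psa is None and isinstance(times, pd.DataFrame):
        df = times
        times, psa = df["time"].to_numpy(), df["P"].to_numpy()
    times = np.asarray(times, dtype=float)
    psa = np.asarray(psa, dtype=float)
    if times.size == 0:
        raise ValueError("empty trajectory")
    nadir = np.minimum.accumulate(psa)
    threshold = rise_factor * nadir
    exceed = (psa > threshold) & (times >= nadir_window)
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(times[0])
    # interpolate the crossing against the (constant-by-then) threshold
    thr = threshold[i]
    p0, p1 = psa[i - 1], psa[i]
    t0, t1 = times[i - 1], times[i]
    if p1 == p0:
        return float(t1)
    frac = (thr - p0) / (p1 - p0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t0 + frac * (t1 - t0))
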