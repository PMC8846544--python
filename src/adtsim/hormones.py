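"""LHRH / LH / testosterone feedback dynamics and steady-state analysis.

The hormonal cascade is x (LHRH) -> y (LH) -> z (testosterone, TES) with
negative feedback of TES on LHRH through the decreasing production term

    h1(z) = p1 / (1 + b1 z).

Three systems are implemented (state nonnegativity and boundedness hold
along trajectories; every system has a unique positive steady state):

``three``
    dx/dt = h1(z) - d1 x,   dy/dt = p2 x - d2 y,   dz/dt = p3 y - d3 z.

``two``
    The quasi-steady reduction eliminating LH:
    dx/dt = h1(z) - d1 x,   dz/dt = p3 x - d3 z
    (its p3 plays the role of p2 p3 / d2 of the three-variable system but
    is kept as an independent named parameter).

``two_with_drug``
    Leuprolide acts as a competitive inhibitor of LHRH-driven TES
    production:  dx/dt = h1(z) - d1 x,
                 dz/dt = h3(x, L) - d3 z,
    with h3(x, L) = p3 x / (1 + b3 (x + L)).

For ``two_with_drug`` the TES steady state solves the quadratic

    b1 (1+b3 L) z^2 + (1 + b3 L + p1 b3 / d1) z - p1 p3/(d1 d3) = 0,

is strictly decreasing in L with z_inf = 0, while the LHRH steady state
x_L = (p1/d1)/(1 + b1 z_L) increases to p1/d1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "HormoneParams",
    "HormoneState",
    "StabilityReport",
    "h1",
    "h3",
    "steady_state_three",
    "steady_state_two",
    "steady_state_two_with_drug",
    "dzbar_dL",
    "integrate_hormones",
    "local_stability",
]

_SYSTEMS = ("three", "two", "two_with_drug")


@dataclass
class HormoneParams:
    """Production/clearance/feedback parameters; all strictly positive."""

    p1: float = 1.0
    b1: float = 1.0
    d1: float = 1.0
    p2: float = 1.0
    d2: float = 1.0
    p3: float = 1.0
    d3: float = 1.0
    b3: float = 1.0

    def __post_init__(self):
        for name in ("p1", "b1", "d1", "p2", "d2", "p3", "d3", "b3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("p1", "b1", "d1", "p2", "d2", "p3", "d3", "b3")}

    @classmethod
    def from_dict(cls, d: dict) -> "HormoneParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class HormoneState:
    """Hormone levels; y is None for the reduced two-variable systems."""

    x: float
    z: float
    y: float | None = None

    def __post_init__(self):
        vals = [self.x, self.z] + ([] if self.y is None else [self.y])
        if any(v < 0 for v in vals):
            raise ValueError("hormone levels must be nonnegative")


def h1(z, p: HormoneParams):
    """Feedback-inhibited LHRH production, p1/(1 + b1 z)."""
    return p.p1 / (1.0 + p.b1 * np.asarray(z, dtype=float))


def h3(x, L, p: HormoneParams):
    """Drug-competed TES production, p3 x / (1 + b3 (x + L))."""
    x = np.asarray(x, dtype=float)
    return p.p3 * x / (1.0 + p.b3 * (x + L))


def _positive_quadratic_root(A: float, B: float, C: float) -> float:
    """Positive root of A z^2 + B z + C = 0 with A, B > 0 > C."""
    disc = B * B - 4.0 * A * C
    return (-B + math.sqrt(disc)) / (2.0 * A)


def steady_state_three(p: HormoneParams, h1_func=None) -> HormoneState:
    """Unique positive steady state of the three-variable system.

    Solves h1(z) = (d1 d2 d3/(p2 p3)) z — a quadratic for the standard
    h1; a bracketed root-finder covers a user-supplied decreasing
    ``h1_func`` — and back-substitutes x = (d2 d3/(p2 p3)) z,
    y = (d3/p3) z.
    """
    c = p.d1 * p.d2 * p.d3 / (p.p2 * p.p3)
    if h1_func is None:
        z = _positive_quadratic_root(p.b1 * c, c, -p.p1)
    else:
        z = _bracketed_root(lambda zz: h1_func(zz) - c * zz)
    return HormoneState(x=(p.d2 * p.d3 / (p.p2 * p.p3)) * z, z=z, y=(p.d3 / p.p3) * z)


def steady_state_two(p: HormoneParams, h1_func=None) -> tuple:
    """Unique positive steady state (x, z) of the reduced system."""
    c = p.d1 * p.d3 / p.p3
    if h1_func is None:
        z = _positive_quadratic_root(p.b1 * c, c, -p.p1)
    else:
        z = _bracketed_root(lambda zz: h1_func(zz) - c * zz)
    return (p.d3 / p.p3) * z, z


def steady_state_two_with_drug(p: HormoneParams, L: float, h_funcs=None) -> tuple:
    """Steady state (x_L, z_L) of the drug-influenced system at constant L.

    z_L is the positive root of
        b1 (1+b3 L) z^2 + (1+b3 L+p1 b3/d1) z - p1 p3/(d1 d3) = 0
    and x_L = (p1/d1)/(1 + b1 z_L);  z_L is strictly decreasing in L with
    limit 0, x_L strictly increasing with limit p1/d1.
    """
    if L < 0:
        raise ValueError("L must be nonnegative")
    if h_funcs is not None:
        h1f, h3f = h_funcs
        # generic monotone forms: solve h3(x(z), L) = d3 z with
        # x(z) = h1(z)/d1 (decreasing), giving a single sign change.
        def g(zz):
            return h3f(h1f(zz) / p.d1, L) - p.d3 * zz

        z = _bracketed_root(g)
        return h1f(z) / p.d1, z
    A = p.b1 * (1.0 + p.b3 * L)
    B = 1.0 + p.b3 * L + p.p1 * p.b3 / p.d1
    C = -p.p1 * p.p3 / (p.d1 * p.d3)
    z = _positive_quadratic_root(A, B, C)
    x = (p.p1 / p.d1) / (1.0 + p.b1 * z)
    return x, z


def _bracketed_root(g, z_max: float = 1.0) -> float:
    """Root of a function with g(0+) > 0 and eventually negative."""
    while g(z_max) > 0:
        z_max *= 2.0
        if z_max > 1e12:  # pragma: no cover
            raise RuntimeError("failed to bracket the steady state")
    return brentq(g, 1e-15, z_max, xtol=1e-14, rtol=1e-14)


def dzbar_dL(p: HormoneParams, L: float) -> float:
    """d z_L / dL by implicit differentiation of the steady-state quadratic:

        dz/dL = - b3 z (1 + b1 z) / (1 + b3 L + p1 b3/d1 + 2 b1 z (1+b3 L)),

    strictly negative for all L >= 0.
    """
    _, z = steady_state_two_with_drug(p, L)
    num = -p.b3 * z * (1.0 + p.b1 * z)
    den = 1.0 + p.b3 * L + p.p1 * p.b3 / p.d1 + 2.0 * p.b1 * z * (1.0 + p.b3 * L)
    return num / den


def _rhs(system: str, p: HormoneParams, L_of_t):
    if system == "three":

        def rhs(t, s):
            x, y, z = s
            return [
                p.p1 / (1.0 + p.b1 * z) - p.d1 * x,
                p.p2 * x - p.d2 * y,
                p.p3 * y - p.d3 * z,
            ]

    elif system == "two":

        def rhs(t, s):
            x, z = s
            return [p.p1 / (1.0 + p.b1 * z) - p.d1 * x, p.p3 * x - p.d3 * z]

    elif system == "two_with_drug":

        def rhs(t, s):
            x, z = s
            L = L_of_t(t)
            return [
                p.p1 / (1.0 + p.b1 * z) - p.d1 * x,
                p.p3 * x / (1.0 + p.b3 * (x + L)) - p.d3 * z,
            ]

    else:
        raise ValueError(f"unknown system {system!r}; choose from {_SYSTEMS}")
    return rhs


def integrate_hormones(
    p: HormoneParams,
    system: str,
    s0,
    t_grid,
    L_of_t=0.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the chosen hormone system from a nonnegative start.

    ``s0`` is (x, y, z) for ``three`` and (x, z) otherwise; ``L_of_t``
    may be a constant or a callable t -> L.  Returns the state array of
    shape (n_states, n_times).
    """
    t = np.asarray(t_grid, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("initial hormone state must be nonnegative")
    expected = 3 if system == "three" else 2
    if s0.size != expected:
        raise ValueError(f"system {system!r} needs {expected} initial values")
    L_fun = L_of_t if callable(L_of_t) else (lambda _t, _L=float(L_of_t): _L)
    sol = solve_ivp(
        _rhs(system, p, L_fun), (t[0], t[-1]), s0, t_eval=t,
        rtol=rtol, atol=atol, method="LSODA",
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"hormone integration failed: {sol.message}")
    return sol.y


@dataclass
class StabilityReport:
    """Jacobian spectrum at a steady state (+ Routh–Hurwitz for the 3x3)."""

    steady_state: tuple
    eigenvalues: np.ndarray
    max_real_part: float
    routh_hurwitz: dict | None = None

    @property
    def stable(self) -> bool:
        return self.max_real_part < 0


def local_stability(p: HormoneParams, system: str, L: float = 0.0) -> StabilityReport:
    """Numerical local stability of the unique positive steady state.

    Jacobians are analytic:  dh1/dz = -p1 b1/(1+b1 z)^2 < 0, and for the
    drug system  dh3/dx = p3 (1+b3 L)/(1+b3(x+L))^2 > 0, giving trace
    -(d1+d3) < 0 and positive determinant for the 2x2 case.  For the 3x3
    case Routh–Hurwitz coefficients of the characteristic polynomial are
    reported alongside the eigenvalues.
    """
    if system == "three":
        ss = steady_state_three(p)
        dh1 = -p.p1 * p.b1 / (1.0 + p.b1 * ss.z) ** 2
        J = np.array(
            [
                [-p.d1, 0.0, dh1],
                [p.p2, -p.d2, 0.0],
                [0.0, p.p3, -p.d3],
            ]
        )
        eig = np.linalg.eigvals(J)
        # char poly: lam^3 + a1 lam^2 + a2 lam + a3
        a1 = p.d1 + p.d2 + p.d3
        a2 = p.d1 * p.d2 + p.d1 * p.d3 + p.d2 * p.d3
        a3 = p.d1 * p.d2 * p.d3 - dh1 * p.p2 * p.p3
        rh = {
            "a1": a1,
            "a2": a2,
            "a3": a3,
            "a1a2_minus_a3": a1 * a2 - a3,
            "satisfied": a1 > 0 and a3 > 0 and a1 * a2 > a3,
        }
        return StabilityReport((ss.x, ss.y, ss.z), eig, float(eig.real.max()), rh)
    if system == "two":
        x, z = steady_state_two(p)
        dh1 = -p.p1 * p.b1 / (1.0 + p.b1 * z) ** 2
        J = np.array([[-p.d1, dh1], [p.p3, -p.d3]])
    elif system == "two_with_drug":
        x, z = steady_state_two_with_drug(p, L)
        dh1 = -p.p1 * p.b1 / (1.0 + p.b1 * z) ** 2
        dh3 = p.p3 * (1.0 + p.b3 * L) / (1.0 + p.b3 * (x + L)) ** 2
        J = np.array([[-p.d1, dh1], [dh3, -p.d3]])
    else:
        raise ValueError(f"unknown system {system!r}")
    eig = np.linalg.eigvals(J)
    return StabilityReport((x, z), eig, float(eig.real.max()))
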