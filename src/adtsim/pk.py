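"""Depot leuprolide pharmacokinetics: two formulations plus dosing.

Leuprolide (Lupron) is given as a subcutaneous slow-release depot.  Two
PK formulations are implemented:

1. **Mass-action transit-compartment model.**  A depot D feeds a chain of
   n transit compartments (delayed first-order absorption, rate k_tr)
   and an immediate first-order path (k2), with optional zero-order
   infusion (k3), a central compartment cleared at d_L, and an optional
   peripheral compartment exchanging at rate Q:

       dD/dt   = -beta * D
       dL1/dt  = k_tr D  - k_tr L1
       ...
       dLn/dt  = k_tr L_{n-1} - k_tr Ln
       dLc/dt  = k1 Ln + k2 D + k3 chi(t) - Q Lc + Q Lp - d_L Lc
       dLp/dt  = Q Lc - Q Lp

   Under the simplifications beta = k_tr = k1 the chain has the closed
   forms D(t) = alpha e^{-k1 t}, L_j(t) = alpha k1^j t^j e^{-k1 t}/j!,
   and — collapsing the peripheral compartment and taking the central
   compartment in quasi-steady state (fast clearance) — the single-dose
   concentration

       L(t) = alpha e^{-k1 t} (k2 + k1^{n+1} t^n / n!) / d_L.

   Note d_L * L(t) equals the absorption inflow k1 Ln(t) + k2 D(t)
   exactly; the approximation of the true central compartment is good in
   the regime d_L >> k1.

2. **Diffusion (microsphere) model.**  The depot consists of polymer
   microspheres of radius R uniformly loaded with drug (total mass M0)
   that diffuses out (coefficient Dc) with a perfect-sink boundary.
   The mass remaining inside the sphere is the classical series

       M_in(t) = (6 M0 / pi^2) * sum_n exp(-n^2 pi^2 rho t) / n^2,

   with release rate rho = Dc/R^2 (1/day).  With the theta-type series
   psi(x) = sum_{n>=1} exp(-pi^2 n^2 x), the released-drug balance is

       dM_out/dt = 6 rho M0 psi(rho t) - d_L M_out,

   and plasma drug follows  dL/dt = k psi(rho_eff t) - d_L L  per dose,
   with superposition across doses (per-dose elapsed-time clocks).

The series psi needs O(x^{-1/2}) terms naively as x -> 0; for x < 0.05
we use the exact Jacobi/Poisson-summation identity

    psi(x) = (1 + 2 sum_{n>=1} e^{-n^2/x}) / (2 sqrt(pi x)) - 1/2,

whose correction terms are below 1e-9 there, so psi is computed
accurately for arbitrarily small positive x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.special import gammaln

__all__ = [
    "MassActionPKParams",
    "DiffusionPKParams",
    "DoseSchedule",
    "STANDARD_DEPOTS",
    "standard_schedule",
    "transit_closed_form",
    "mass_action_concentration",
    "integrate_mass_action",
    "MassActionSolution",
    "psi",
    "sphere_drug_mass",
    "released_mass",
    "integrate_diffusion_pk",
    "PKTrajectory",
]

#: The four labelled depot presets: name -> (dose mg, inter-dose interval days).
STANDARD_DEPOTS = {
    "7.5mg_q4w": (7.5, 28.0),
    "22.5mg_q12w": (22.5, 84.0),
    "30mg_q16w": (30.0, 112.0),
    "45mg_q24w": (45.0, 168.0),
}


@dataclass
class DoseSchedule:
    """Depot injections as (time_days, dose_mg) pairs, times non-decreasing."""

    doses: list
    schedule_id: str = "custom"

    def __post_init__(self):
        self.doses = [(float(t), float(d)) for t, d in self.doses]
        times = [t for t, _ in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")
        if any(d <= 0 for _, d in self.doses):
            raise ValueError("doses must be positive")

    @classmethod
    def regular(cls, dose_mg, interval_days, n_doses, start=0.0, schedule_id=None):
        doses = [(start + i * interval_days, dose_mg) for i in range(n_doses)]
        return cls(doses, schedule_id or f"{dose_mg}mg_q{interval_days:g}d")


def standard_schedule(name: str, n_doses: int = 4) -> DoseSchedule:
    """One of the four labelled depots as a repeating schedule."""
    dose, interval = STANDARD_DEPOTS[name]
    return DoseSchedule.regular(dose, interval, n_doses, schedule_id=name)


@dataclass
class MassActionPKParams:
    """Transit-compartment parameterization.

    ``alpha`` is the fraction of each dose entering the depot D;
    ``beta``/``k_tr`` default to ``k1`` (the simplifying assumptions
    beta = k_tr = k1 under which the closed forms hold); Q = 0 collapses
    the peripheral compartment (the default).
    """

    k1: float
    k2: float
    d_L: float
    n_transit: int = 3
    alpha: float = 1.0
    k3: float = 0.0
    Q: float = 0.0
    beta: float | None = None
    k_tr: float | None = None

    def __post_init__(self):
        if self.beta is None:
            self.beta = self.k1
        if self.k_tr is None:
            self.k_tr = self.k1
        for name in ("k1", "k2", "d_L", "alpha", "k3", "Q", "beta", "k_tr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.d_L <= 0:
            raise ValueError("d_L must be positive")
        if self.n_transit < 1:
            raise ValueError("n_transit must be >= 1")

    @property
    def simplified(self) -> bool:
        """True when beta = k_tr = k1 (closed forms apply)."""
        return self.beta == self.k_tr == self.k1


def transit_closed_form(t, j: int, alpha: float, k1: float):
    """Closed-form transit compartment L_j(t) = alpha k1^j t^j e^{-k1 t}/j!.

    ``j = 0`` returns the depot D(t) = alpha e^{-k1 t} instead.  Requires
    the chain simplification beta = k_tr = k1 and a single dose at t = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if j < 0:
        raise ValueError("j must be >= 0")
    if j == 0:
        out = alpha * np.exp(-k1 * t)
    else:
        with np.errstate(divide="ignore"):
            logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), -np.inf)
        out = alpha * np.exp(j * math.log(k1) + j * logt - k1 * t - gammaln(j + 1))
        out = np.where(t > 0, out, 0.0)
    return out if out.ndim else float(out)


def mass_action_concentration(t, p: MassActionPKParams):
    """Single-dose quasi-steady central concentration

        L(t) = alpha e^{-k1 t} (k2 + k1^{n+1} t^n / n!) / d_L,

    valid under beta = k_tr = k1, k3 = 0, collapsed peripheral
    compartment, and fast central clearance (d_L >> k1).  The identity
    d_L L(t) = k1 L_n(t) + k2 D(t) holds exactly.
    """
    t = np.asarray(t, dtype=float)
    n = p.n_transit
    poly = p.k2 + np.exp(
        (n + 1) * math.log(p.k1)
        + n * np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), 0.0)
        - gammaln(n + 1)
    ) * np.where(t > 0, 1.0, 0.0)
    poly = np.where(t > 0, poly, p.k2)
    out = p.alpha * np.exp(-p.k1 * t) * poly / p.d_L
    return out if out.ndim else float(out)


@dataclass
class MassActionSolution:
    """Trajectories of every compartment of the transit-chain system."""

    times: np.ndarray
    depot: np.ndarray
    transit: np.ndarray  # shape (n_transit, n_times)
    central: np.ndarray
    peripheral: np.ndarray
    params: MassActionPKParams

    @property
    def inflow(self) -> np.ndarray:
        """Absorption inflow into the central compartment, k1 Ln + k2 D."""
        return self.params.k1 * self.transit[-1] + self.params.k2 * self.depot

    @property
    def quasi_steady(self) -> np.ndarray:
        """Quasi-steady central concentration, inflow / d_L."""
        return self.inflow / self.params.d_L


def integrate_mass_action(
    p: MassActionPKParams,
    schedule: DoseSchedule,
    t_grid,
    infusion_windows=(),
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> MassActionSolution:
    """Integrate the full linear transit-chain system with impulsive dosing.

    Each dose at time t_d adds ``alpha * dose`` to the depot D.  The
    zero-order term k3 chi(t) is active inside ``infusion_windows``
    (list of (t0, t1) pairs), default off.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    n = p.n_transit
    nstate = n + 3  # D, L1..Ln, Lc, Lp

    def chi(ti):
        return 1.0 if any(t0 <= ti < t1 for t0, t1 in infusion_windows) else 0.0

    def rhs(ti, s):
        D = s[0]
        L = s[1 : n + 1]
        Lc, Lp = s[n + 1], s[n + 2]
        ds = np.empty(nstate)
        ds[0] = -p.beta * D
        ds[1] = p.k_tr * D - p.k_tr * L[0]
        for i in range(1, n):
            ds[1 + i] = p.k_tr * L[i - 1] - p.k_tr * L[i]
        ds[n + 1] = (
            p.k1 * L[-1] + p.k2 * D + p.k3 * chi(ti) - p.Q * Lc + p.Q * Lp - p.d_L * Lc
        )
        ds[n + 2] = p.Q * Lc - p.Q * Lp
        return ds

    t_start = min(t[0], min((td for td, _ in schedule.doses), default=t[0]))
    breaks = sorted(
        {td for td, _ in schedule.doses if t_start <= td <= t[-1]}
        | {w for win in infusion_windows for w in win if t_start <= w <= t[-1]}
    )
    segments = np.concatenate(([t_start], breaks, [t[-1]]))
    segments = np.unique(segments)

    state = np.zeros(nstate)
    out = np.zeros((nstate, t.size))
    done = np.zeros(t.size, dtype=bool)
    dose_map = {}
    for td, d in schedule.doses:
        dose_map[td] = dose_map.get(td, 0.0) + d

    for a, b in zip(segments[:-1], segments[1:]):
        if a in dose_map:
            state = state.copy()
            state[0] += p.alpha * dose_map[a]
        # a point exactly at a dose time reports the post-impulse state,
        # so segment-end points belong to the *next* segment (except the last)
        last = b == segments[-1]
        mask = (t >= a) & ((t <= b) if last else (t < b)) & ~done
        t_eval = t[mask]
        if mask.any() and t_eval[0] == a:
            out[:, np.flatnonzero(mask)[0]] = state
            done[np.flatnonzero(mask)[0]] = True
            mask = (t > a) & ((t <= b) if last else (t < b)) & ~done
            t_eval = t[mask]
        grid = np.unique(np.concatenate((t_eval, [b])))
        sol = solve_ivp(
            rhs, (a, b), state, t_eval=grid, rtol=rtol, atol=atol, method="LSODA"
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"PK integration failed: {sol.message}")
        if t_eval.size:
            idx = np.searchsorted(sol.t, t_eval)
            out[:, mask] = sol.y[:, idx]
            done[mask] = True
        state = sol.y[:, -1]
    return MassActionSolution(
        times=t,
        depot=out[0],
        transit=out[1 : n + 1],
        central=out[n + 1],
        peripheral=out[n + 2],
        params=p,
    )


# ---------------------------------------------------------------------------
# diffusion / microsphere formulation
# ---------------------------------------------------------------------------

_PI2 = math.pi**2


def psi(x, tol: float = 1e-14):
    """theta-type series psi(x) = sum_{n>=1} exp(-pi^2 n^2 x), x > 0.

    The direct series is truncated when the next (positive, decreasing)
    term drops below ``tol``; for x < 0.05 the exact Poisson-summation
    form is used instead, so small arguments cost O(1) terms.
    """
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(float)
    if np.any(arr <= 0):
        raise ValueError("psi requires x > 0 (the series diverges at 0)")
    out = np.empty_like(arr)
    small = arr < 0.05
    if small.any():
        xs = arr[small]
        s = np.zeros_like(xs)
        for n in range(1, 40):
            term = np.exp(-(n * n) / xs)
            s += term
            if term.max() < tol:
                break
        out[small] = (1.0 + 2.0 * s) / (2.0 * np.sqrt(np.pi * xs)) - 0.5
    if (~small).any():
        xl = arr[~small]
        s = np.zeros_like(xl)
        for n in range(1, 10000):
            term = np.exp(-_PI2 * n * n * xl)
            s += term
            if term.max() < tol:
                break
        out[~small] = s
    return float(out[0]) if scalar else out


@dataclass
class DiffusionPKParams:
    """Microsphere-release parameterization.

    Parameters
    ----------
    M0 : float
        Reference depot drug mass (mg); doses scale linearly against it.
    release_rate : float
        rho = Dc/R^2 (1/day), the diffusive release rate.
    k : float
        Scaling of released drug into plasma concentration (conc/day).
    d_L : float
        Plasma clearance (1/day).
    a_rel : float or None
        If set, the psi argument uses the rate ``a_rel / M0`` instead of
        ``release_rate`` (the two are interchangeable via the
        identification a_rel/M0 <-> Dc/R^2; they are kept independent
        because the release notation leaves the dimensional bookkeeping
        of the psi argument open).
    """

    M0: float
    release_rate: float
    k: float
    d_L: float
    a_rel: float | None = None

    def __post_init__(self):
        for name in ("M0", "release_rate", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_L < 0:
            raise ValueError("d_L must be nonnegative")
        if self.a_rel is not None and self.a_rel <= 0:
            raise ValueError("a_rel must be positive when given")

    @property
    def effective_rate(self) -> float:
        """Rate appearing in the psi argument (1/day)."""
        return self.a_rel / self.M0 if self.a_rel is not None else self.release_rate


def sphere_drug_mass(t, p: DiffusionPKParams, tol: float = 1e-12):
    """Drug mass remaining inside the microsphere,

        M_in(t) = (6 M0/pi^2) sum_n exp(-n^2 pi^2 rho t)/n^2.

    M_in(0) = M0 exactly (sum 1/n^2 = pi^2/6) and M_in is non-increasing.
    For rho*t < 0.01 the early-time square-root release law
    M_in/M0 = 1 - 6 sqrt(rho t/pi) + 3 rho t is used (its neglected
    terms are below e^{-1/(rho t)} there), avoiding the slowly
    converging series.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).astype(float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    s = p.release_rate * t
    out = np.empty_like(s)
    small = s < 0.01
    if small.any():
        ss = s[small]
        out[small] = p.M0 * (1.0 - 6.0 * np.sqrt(ss / np.pi) + 3.0 * ss)
    if (~small).any():
        sl = s[~small]
        acc = np.zeros_like(sl)
        for n in range(1, 100000):
            term = np.exp(-_PI2 * n * n * sl) / (n * n)
            acc += term
            if term.max() < tol:
                break
        out[~small] = (6.0 * p.M0 / _PI2) * acc
    return float(out[0]) if scalar else out


def _convolve_psi(tau: float, rate: float, d_L: float) -> float:
    """integral_0^tau psi(rate*s) exp(-d_L (tau - s)) ds.

    Substituting s = v^2 removes the integrable s^{-1/2} singularity of
    psi at s = 0 (the integrand tends to 1/sqrt(pi*rate) there).
    """
    if tau <= 0:
        return 0.0

    def integrand(v):
        xx = max(rate * v * v, 1e-300)
        return 2.0 * v * psi(xx) * math.exp(-d_L * (tau - v * v))

    val, _ = quad(integrand, 0.0, math.sqrt(tau), epsabs=1e-13, epsrel=1e-11, limit=300)
    return val


def released_mass(t, p: DiffusionPKParams):
    """Drug mass outside the sphere, dM_out/dt = 6 rho M0 psi(rho t) - d_L M_out.

    Computed by adaptive quadrature of the convolution integral (an
    independent route from the series of :func:`sphere_drug_mass`); with
    d_L = 0 mass balance gives M_in(t) + M_out(t) = M0.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).astype(float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    rho = p.release_rate
    out = np.array([6.0 * rho * p.M0 * _convolve_psi(ti, rho, p.d_L) for ti in t])
    return float(out[0]) if scalar else out


@dataclass
class PKTrajectory:
    """Plasma drug concentration trajectory."""

    times: np.ndarray
    concentration: np.ndarray
    schedule_id: str = "custom"

    def interpolator(self):
        """L(t) as a callable (linear interpolation, 0 outside the grid)."""
        times, conc = self.times, self.concentration

        def L_of_t(ti):
            return float(np.interp(ti, times, conc, left=0.0, right=conc[-1]))

        return L_of_t


def integrate_diffusion_pk(
    p: DiffusionPKParams, schedule: DoseSchedule, t_grid
) -> PKTrajectory:
    """Plasma leuprolide under microsphere release and multi-dose input:

        dL/dt = sum_doses k (dose/M0) psi(rho_eff (t - t_dose)) - d_L L,
        L(0) = 0,

    each dose running on its own elapsed-time clock (superposition of the
    linear system).  Evaluated by exact convolution quadrature per dose;
    at t equal to a dose time the contribution of that dose is the
    right-limit 0 (the psi argument is kept positive inside the
    quadrature).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be non-decreasing")
    rate = p.effective_rate
    conc = np.zeros_like(t)
    for td, dose in schedule.doses:
        amp = p.k * dose / p.M0
        for i, ti in enumerate(t):
            tau = ti - td
            if tau > 0:
                conc[i] += amp * _convolve_psi(tau, rate, p.d_L)
    return PKTrajectory(times=t, concentration=conc, schedule_id=schedule.schedule_id)
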