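"""Shared fixtures and independent numerical oracles."""

import math

import numpy as np
import pytest
from scipy.linalg import solve_banded

import adtsim as ad


@pytest.fixture
def log_power_law():
    return ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})


@pytest.fixture
def unit_hormones():
    """All production/clearance/feedback parameters equal to 1."""
    return ad.HormoneParams()


@pytest.fixture
def strong_cascade_hormones():
    """b1 = b3 = p1/d1 = 1, p3/d3 = 20: a strongly amplifying cascade
    with untreated testosterone steady state sqrt(21) - 1."""
    return ad.HormoneParams(p1=1, d1=1, b1=1, b3=1, p3=20, d3=1)


def crank_nicolson_sphere_mass(t_eval, release_rate, M0, n_r=400, n_t_per_unit=4000):
    """Independent PDE oracle: drug mass left in a sphere with perfect-sink
    boundary, by Crank–Nicolson on u = r*rho (so u_t = Dc u_rr, u(0) =
    u(R) = 0, u(r,0) = rho0 r), with R = 1 and Dc = release_rate.
    """
    R = 1.0
    Dc = release_rate
    rho0 = M0 / ((4.0 / 3.0) * math.pi * R**3)
    r = np.linspace(0.0, R, n_r + 1)
    dr = r[1] - r[0]
    u = rho0 * r.copy()
    u[0] = u[-1] = 0.0
    t_eval = np.asarray(t_eval, dtype=float)
    t_end = float(t_eval.max())
    n_steps = max(int(n_t_per_unit * t_end * Dc), 200)
    dt = t_end / n_steps
    lam = Dc * dt / (2.0 * dr * dr)
    n_in = n_r - 1  # interior nodes
    # (I - lam*T) u^{n+1} = (I + lam*T) u^n with T the 1-d Laplacian stencil
    ab = np.zeros((3, n_in))
    ab[0, 1:] = -lam
    ab[1, :] = 1.0 + 2.0 * lam
    ab[2, :-1] = -lam
    out = np.empty_like(t_eval)
    t_now = 0.0
    targets = sorted((tv, i) for i, tv in enumerate(t_eval))
    ti = 0
    for step in range(n_steps + 1):
        while ti < len(targets) and t_now >= targets[ti][0] - 1e-12:
            ui = u.copy()
            mass = 4.0 * math.pi * np.trapezoid(ui * r, r)
            out[targets[ti][1]] = mass
            ti += 1
        if ti >= len(targets):
            break
        rhs = u[1:-1] + lam * (u[2:] - 2.0 * u[1:-1] + u[:-2])
        u[1:-1] = solve_banded((1, 1), ab, rhs)
        t_now += dt
    return out


@pytest.fixture
def sphere_pde_oracle():
    return crank_nicolson_sphere_mass
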