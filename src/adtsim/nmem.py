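"""Nonlinear mixed-effects estimation of growth-law parameters.

The model for patient i, observation j:

    y_ij = f(phi_i, t_ij; y0_i) + eps_ij,      eps_ij ~ N(0, sigma^2),

where y = ln(P/P_R), f is the log-scale solution of the chosen growth
law started at the patient's (unobserved) baseline y0_i, and the
individual parameter vector phi_i equals the population fixed effects
beta except that each *random* parameter k carries a patient-level
perturbation on the log scale,

    phi_ik = beta_k * exp(b_ik),               b_ik ~ N(0, omega_k^2)

(diagonal random-effect covariance).  Baselines y0_i are per-patient
nuisance parameters with a flat prior, integrated out together with the
random effects by a Laplace approximation — anchoring trajectories on
the noisy first observation instead would inject an errors-in-variables
bias into the curvature parameters that does not vanish with cohort
size.  For each patient the joint mode u_i = (y0_i, b_i) of

    h_i(u) = SSR_i(u)/(2 sigma^2) + sum_k b_k^2/(2 omega_k^2)

is found by a nested, vectorized, warm-started damped-Newton iteration,
and the patient's contribution to the negative log marginal likelihood
is

    (n_i/2) ln(2 pi sigma^2) + h_i(u_hat)
        + (1/2) ln( prod_k omega_k^2 * det H_i / (2 pi) ),

with H_i the Hessian of h_i at the mode.  A first-order (FO)
alternative linearizes f in b around 0 (baselines still profiled) and
evaluates the resulting Gaussian marginal exactly.  Individual
parameters are reported as posterior modes.

Observations censored at the detection level P_R are dropped by default
(optionally kept floored at P_R).  Model-comparison metrics (MSE and
R^2 on the log scale against individual-mode predictions, NLL,
AIC = 2k + 2 NLL, BIC = k ln n + 2 NLL) count
k = fixed effects + random-effect variances + residual variance; the
integrated per-patient baselines are not counted, and the convention is
carried in every report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import Cohort
from .growth import (
    CLOSED_FORM_LAWS,
    GrowthLawSpec,
    _predict_log_ratio_ode,
    closed_form_log_ratio,
)

__all__ = [
    "NmemSpec",
    "FitResult",
    "fit_nmem",
    "fit_metrics",
    "model_selection",
    "default_model_suite",
]

_BIG = 1e12

# transform applied to each fixed effect for unconstrained optimization
_LOGIT_PARAMS = {("log_power", "gamma")}
_IDENTITY_PARAMS = {"k0"}


def _transform(law_name: str, pname: str, value: float) -> float:
    if (law_name, pname) in _LOGIT_PARAMS:
        return math.log(value / (1.0 - value))
    if pname in _IDENTITY_PARAMS:
        return value
    return math.log(value)


def _untransform(law_name: str, pname: str, value: float) -> float:
    if (law_name, pname) in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-value))
    if pname in _IDENTITY_PARAMS:
        return value
    return math.exp(value)


@dataclass
class NmemSpec:
    """Fitting specification: which law, which parameters are random,
    how censored points and initialization are handled."""

    law: GrowthLawSpec
    random_params: tuple = ("a",)
    censored: str = "drop"  # or "floor"
    method: str = "laplace"  # or "fo"
    n_starts: int = 5
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self):
        self.random_params = tuple(self.random_params)
        for rp in self.random_params:
            if rp not in self.law.params:
                raise ValueError(
                    f"random parameter {rp!r} not in the {self.law.name} law"
                )
        if self.censored not in ("drop", "floor"):
            raise ValueError("censored must be 'drop' or 'floor'")
        if self.method not in ("laplace", "fo"):
            raise ValueError("method must be 'laplace' or 'fo'")


@dataclass
class FitResult:
    """Population fit: fixed effects, variance components, individual
    modes, and fit-quality metrics."""

    law_name: str
    fixed_estimates: dict
    random_variances: dict
    residual_sd: float
    individual_modes: pd.DataFrame
    nll: float
    mse: float
    r2: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    predictions: pd.DataFrame
    param_count_convention: str = (
        "n_params = fixed effects + random-effect variances + residual "
        "variance; per-patient baselines are integrated out, not counted"
    )
    nll_trace: np.ndarray | None = None


class _CohortArrays:
    """Flattened per-observation arrays for vectorized prediction."""

    def __init__(self, cohort: Cohort, censored: str):
        pids, t_list, y_list, n_list, yfirst = [], [], [], [], []
        dropped = 0
        for pid, g in cohort.patients():
            if censored == "drop":
                g = g[~g["censored"].astype(bool)]
            t = g["time_days"].to_numpy(dtype=float)
            v = g["psa_ng_ml"].to_numpy(dtype=float)
            if len(t) < 2:
                dropped += 1
                continue
            y = np.log(v / cohort.p_r)
            pids.append(pid)
            t_list.append(t - t[0])  # times relative to the first visit
            y_list.append(y)
            n_list.append(len(t))
            yfirst.append(y[0])
        if dropped:
            warnings.warn(f"{dropped} patient(s) dropped (fewer than 2 usable points)")
        if len(pids) < 2:
            raise ValueError("need at least 2 patients with >= 2 observations each")
        self.pids = pids
        self.M = len(pids)
        self.n = np.array(n_list)
        self.t = np.concatenate(t_list)
        self.y = np.concatenate(y_list)
        self.y_first = np.array(yfirst)
        self.pidx = np.concatenate([np.full(k, i) for i, k in enumerate(n_list)])
        self.ptr = np.concatenate(([0], np.cumsum(self.n)[:-1]))
        self.N = self.t.size


def _predict_flat(
    law: GrowthLawSpec, arrays: _CohortArrays, params_flat: dict, y0_flat: np.ndarray
) -> np.ndarray:
    if law.name in CLOSED_FORM_LAWS:
        with np.errstate(all="ignore"):
            return closed_form_log_ratio(law.name, params_flat, law.p_r, y0_flat, arrays.t)
    # per-patient ODE fallback
    out = np.empty(arrays.N)
    for i in range(arrays.M):
        sel = arrays.pidx == i
        p_i = {
            k: (float(np.asarray(v)[sel][0]) if np.ndim(v) else float(v))
            for k, v in params_flat.items()
        }
        law_i = replace(law, params=p_i)
        out[sel] = _predict_log_ratio_ode(law_i, float(y0_flat[sel][0]), arrays.t[sel])
    return out


class _Objective:
    """Marginal negative log-likelihood with nested per-patient modes.

    The inner state per patient is u = (y0, b_1..b_q); modes are found by
    a vectorized damped Newton with numeric derivatives, warm-started
    across outer evaluations (each patient's inner problem is
    independent, so warm starts preserve patient-order invariance).
    """

    def __init__(self, spec: NmemSpec, arrays: _CohortArrays):
        self.spec = spec
        self.arrays = arrays
        self.pnames = list(spec.law.params.keys())
        self.q = len(spec.random_params)
        self.d = 1 + self.q  # inner dimension: baseline + random effects
        self.warm = np.zeros((arrays.M, self.d))
        self.warm[:, 0] = arrays.y_first
        self.best = math.inf
        self.trace = []

    # -- parameter vector layout: [transformed fixed] + [log sigma] + [log omega_k]
    def pack(self, fixed: dict, sigma: float, omegas: dict) -> np.ndarray:
        vec = [_transform(self.spec.law.name, k, fixed[k]) for k in self.pnames]
        vec.append(math.log(sigma))
        vec += [math.log(omegas[k]) for k in self.spec.random_params]
        return np.array(vec)

    def unpack(self, vec: np.ndarray):
        nfix = len(self.pnames)
        fixed = {
            k: _untransform(self.spec.law.name, k, float(v))
            for k, v in zip(self.pnames, vec[:nfix])
        }
        sigma = math.exp(float(vec[nfix]))
        omegas = {
            k: math.exp(float(v))
            for k, v in zip(self.spec.random_params, vec[nfix + 1 :])
        }
        return fixed, sigma, omegas

    def _flat_params(self, fixed: dict, u: np.ndarray) -> dict:
        a = self.arrays
        flat = {}
        for k in self.pnames:
            if k in self.spec.random_params:
                j = 1 + self.spec.random_params.index(k)
                flat[k] = fixed[k] * np.exp(u[a.pidx, j])
            else:
                flat[k] = fixed[k]
        return flat

    def _penalized(self, fixed, sigma, omegas, u: np.ndarray) -> np.ndarray:
        """Per-patient penalized objective h_i(u); u has shape (M, d)."""
        a = self.arrays
        pred = _predict_flat(self.spec.law, a, self._flat_params(fixed, u), u[a.pidx, 0])
        res2 = (a.y - pred) ** 2
        res2 = np.where(np.isfinite(res2), res2, _BIG)
        h = np.add.reduceat(res2, a.ptr) / (2.0 * sigma**2)
        for j, k in enumerate(self.spec.random_params):
            h = h + u[:, 1 + j] ** 2 / (2.0 * omegas[k] ** 2)
        return h

    def modes(self, fixed, sigma, omegas, max_iter: int = 30, tol: float = 1e-8):
        """Vectorized damped Newton over u; returns (u_hat, h(u_hat),
        Hessians of shape (M, d, d))."""
        M, d = self.arrays.M, self.d
        step_h = 1e-4
        u = self.warm.copy()

        def H_of(uu):
            return self._penalized(fixed, sigma, omegas, uu)

        f0 = H_of(u)
        # fall back to a neutral start when the warm start is degenerate
        bad = ~np.isfinite(f0) | (f0 > _BIG / 2)
        if bad.any():
            u[bad, 0] = self.arrays.y_first[bad]
            u[bad, 1:] = 0.0
            f0 = H_of(u)

        eye = np.eye(d)
        for _ in range(max_iter):
            grad = np.empty((M, d))
            hess = np.empty((M, d, d))
            f_plus = np.empty((M, d))
            f_minus = np.empty((M, d))
            for r in range(d):
                fp = H_of(u + step_h * eye[r])
                fm = H_of(u - step_h * eye[r])
                f_plus[:, r], f_minus[:, r] = fp, fm
                grad[:, r] = (fp - fm) / (2 * step_h)
                hess[:, r, r] = (fp - 2 * f0 + fm) / step_h**2
            for r in range(d):
                for c in range(r + 1, d):
                    fpp = H_of(u + step_h * (eye[r] + eye[c]))
                    fmm = H_of(u - step_h * (eye[r] + eye[c]))
                    cross = (fpp - 2 * f0 + fmm) / (2 * step_h**2) - 0.5 * (
                        hess[:, r, r] + hess[:, c, c]
                    )
                    hess[:, r, c] = hess[:, c, r] = cross
            # regularize to positive definite and solve for the step (batched)
            eigmin = np.linalg.eigvalsh(hess)[:, 0]
            ridge = np.maximum(1e-8, 1e-8 - eigmin) + np.where(eigmin < 1e-8, 1e-6, 0.0)
            hreg = hess + ridge[:, None, None] * eye
            step = -np.linalg.solve(hreg, grad[:, :, None])[:, :, 0]
            norm = np.maximum(np.abs(step).max(axis=1, keepdims=True), 1e-300)
            step = np.where(norm > 2.0, step * (2.0 / norm), step)
            worse = np.ones(M, dtype=bool)
            for _ in range(8):
                un = u + step
                fn = H_of(un)
                worse = fn > f0 + 1e-13
                if not worse.any():
                    break
                step = np.where(worse[:, None], 0.5 * step, step)
            moved = ~worse
            u = np.where(moved[:, None], un, u)
            f0 = np.where(moved, fn, f0)
            if np.max(np.abs(np.where(moved[:, None], step, 0.0))) < tol:
                break
        # final Hessian at the mode
        hess = np.empty((M, d, d))
        f_p = np.empty((M, d))
        f_m = np.empty((M, d))
        for r in range(d):
            f_p[:, r] = H_of(u + step_h * eye[r])
            f_m[:, r] = H_of(u - step_h * eye[r])
            hess[:, r, r] = np.maximum((f_p[:, r] - 2 * f0 + f_m[:, r]) / step_h**2, 1e-10)
        for r in range(d):
            for c in range(r + 1, d):
                fpp = H_of(u + step_h * (eye[r] + eye[c]))
                fmm = H_of(u - step_h * (eye[r] + eye[c]))
                cross = (fpp - 2 * f0 + fmm) / (2 * step_h**2) - 0.5 * (
                    hess[:, r, r] + hess[:, c, c]
                )
                hess[:, r, c] = hess[:, c, r] = cross
        self.warm = u.copy()
        return u, f0, hess

    def nll(self, vec: np.ndarray) -> float:
        try:
            fixed, sigma, omegas = self.unpack(vec)
        except (OverflowError, ValueError):
            return _BIG
        if not all(
            np.isfinite(list(fixed.values()) + [sigma] + list(omegas.values()))
        ):
            return _BIG
        if self.spec.law.name == "log_power" and not 0 < fixed["gamma"] < 1:
            return _BIG
        a = self.arrays
        if self.spec.method == "fo" and self.q == 1:
            val = self._nll_fo(fixed, sigma, omegas)
        else:
            u, h_mode, hess = self.modes(fixed, sigma, omegas)
            det = np.linalg.det(hess)
            det = np.where(det > 1e-300, det, 1e-300)
            om2 = np.prod([omegas[k] ** 2 for k in self.spec.random_params]) if self.q else 1.0
            per = (
                a.n / 2.0 * math.log(2.0 * math.pi * sigma**2)
                + h_mode
                + 0.5 * np.log(om2 * det / (2.0 * math.pi))
            )
            val = float(np.sum(np.sort(per)))
        if not np.isfinite(val):
            return _BIG
        if val < self.best:
            self.best = val
        self.trace.append(self.best)
        return val

    def _nll_fo(self, fixed, sigma, omegas) -> float:
        """First-order marginal: profile the baselines at b = 0, then
        linearize the prediction in b."""
        a = self.arrays
        omega = omegas[self.spec.random_params[0]]
        u, _, hess = self.modes(fixed, sigma, {k: 1e8 for k in omegas})
        u = u.copy()
        u[:, 1:] = 0.0
        h = 1e-4
        up, um = u.copy(), u.copy()
        up[:, 1] += h
        um[:, 1] -= h
        pred0 = _predict_flat(self.spec.law, a, self._flat_params(fixed, u), u[a.pidx, 0])
        predp = _predict_flat(self.spec.law, a, self._flat_params(fixed, up), up[a.pidx, 0])
        predm = _predict_flat(self.spec.law, a, self._flat_params(fixed, um), um[a.pidx, 0])
        J = (predp - predm) / (2 * h)
        r = a.y - pred0
        if not (np.isfinite(pred0).all() and np.isfinite(J).all()):
            return _BIG
        JJ = np.add.reduceat(J * J, a.ptr)
        Jr = np.add.reduceat(J * r, a.ptr)
        rr = np.add.reduceat(r * r, a.ptr)
        s2 = sigma**2
        denom = s2 + omega**2 * JJ
        quad = rr / s2 - (omega**2 / s2) * Jr**2 / denom
        logdet = a.n * math.log(s2) + np.log(denom / s2)
        # Laplace factor for the profiled baselines
        h00 = np.maximum(hess[:, 0, 0], 1e-10)
        per = 0.5 * (
            a.n * math.log(2 * math.pi) + logdet + quad + np.log(h00 / (2 * math.pi))
        )
        return float(np.sum(np.sort(per)))


def _heuristic_init(spec: NmemSpec, arrays: _CohortArrays):
    """Data-driven starting values from per-patient linear log-PSA fits."""
    slopes, resid_sds = [], []
    for i in range(arrays.M):
        sel = arrays.pidx == i
        t, y = arrays.t[sel], arrays.y[sel]
        A = np.vstack([t, np.ones_like(t)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        slopes.append(coef[0])
        resid_sds.append(np.std(y - A @ coef))
    slopes = np.asarray(slopes)
    med_slope = max(float(np.median(slopes)), 1e-5)
    y_all = arrays.y
    ymax, ybar = float(y_all.max()), float(y_all.mean())
    sigma0 = max(float(np.median(resid_sds)), 0.05)
    pos = slopes[slopes > 1e-8]
    omega0 = min(max(float(np.std(np.log(pos))) if pos.size > 1 else 0.3, 0.1), 2.0)

    name = spec.law.name
    p_r = spec.law.p_r
    fixed = dict(spec.law.params)
    kappa0 = max(ymax, 0.0) + 0.7
    if name == "exponential":
        fixed["a"] = med_slope
    elif name == "gompertz":
        fixed["K"] = p_r * math.exp(kappa0)
        fixed["a"] = med_slope / max(kappa0 - ybar, 0.1)
    elif name in ("logistic", "generalized_logistic"):
        fixed["K"] = p_r * math.exp(kappa0)
        fixed["a"] = med_slope
    elif name == "log_power":
        fixed.setdefault("b", 1.0)
        fixed.setdefault("gamma", 0.5)
        fixed["a"] = med_slope / (1.0 + fixed["b"] * max(ybar, 0.0)) ** fixed["gamma"]
    elif name == "time_modulated":
        fixed["a"] = med_slope * math.exp(-fixed.get("gamma", 0.5) * max(ybar, 0.0))
    omegas = {k: omega0 for k in spec.random_params}
    return fixed, sigma0, omegas


def fit_nmem(cohort: Cohort, spec: NmemSpec) -> FitResult:
    """Maximum marginal-likelihood population fit of a growth law.

    Multi-start Nelder–Mead over the transformed fixed effects, residual
    SD, and random-effect SDs, with nested per-patient mode finding; the
    best start's likelihood is retained.  Deterministic given the data
    and ``spec.seed``, and invariant to patient ordering (per-patient
    contributions are accumulated in sorted order; each patient's inner
    problem is independent of the others).
    """
    arrays = _CohortArrays(cohort, spec.censored)
    obj = _Objective(spec, arrays)
    fixed0, sigma0, omegas0 = _heuristic_init(spec, arrays)
    x0 = obj.pack(fixed0, sigma0, omegas0)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    starts = [x0]
    for _ in range(max(spec.n_starts - 1, 0)):
        starts.append(x0 + rng.normal(0.0, 0.4, size=x0.size))

    best = None
    for s in starts:
        res = minimize(
            obj.nll,
            s,
            method="Nelder-Mead",
            options={
                "maxiter": spec.max_iter,
                "xatol": 1e-4,
                "fatol": 1e-6,
                "adaptive": True,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    fixed, sigma, omegas = obj.unpack(best.x)
    nll_val = float(best.fun)
    converged = bool(np.isfinite(nll_val) and nll_val < _BIG / 2)

    # variance collapse: a random effect shrunk to (numerically) zero
    for k, w in list(omegas.items()):
        if w < 1e-6:
            warnings.warn(
                f"random-effect SD for {k!r} collapsed to ~0; "
                "treating it as a fixed effect"
            )
            omegas[k] = 0.0

    u_hat, _, _ = obj.modes(fixed, sigma, {k: max(w, 1e-8) for k, w in omegas.items()})
    pred = _predict_flat(
        spec.law, arrays, obj._flat_params(fixed, u_hat), u_hat[arrays.pidx, 0]
    )

    modes_rows = []
    for i, pid in enumerate(arrays.pids):
        row = {"patient_id": pid, "y0": float(u_hat[i, 0])}
        for j, k in enumerate(spec.random_params):
            row[f"b_{k}"] = float(u_hat[i, 1 + j])
            row[k] = fixed[k] * math.exp(float(u_hat[i, 1 + j]))
        modes_rows.append(row)

    predictions = pd.DataFrame(
        {
            "patient_id": [arrays.pids[i] for i in arrays.pidx],
            "time_days": arrays.t,
            "y_obs": arrays.y,
            "y_pred": pred,
        }
    )
    resid = arrays.y - pred
    mse = float(np.mean(resid**2))
    sst = float(np.sum((arrays.y - arrays.y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else math.nan
    n_params = len(fixed) + len(spec.random_params) + 1
    aic = 2.0 * n_params + 2.0 * nll_val
    bic = n_params * math.log(arrays.N) + 2.0 * nll_val
    return FitResult(
        law_name=spec.law.name,
        fixed_estimates=fixed,
        random_variances={k: w**2 for k, w in omegas.items()},
        residual_sd=sigma,
        individual_modes=pd.DataFrame(modes_rows),
        nll=nll_val,
        mse=mse,
        r2=r2,
        aic=aic,
        bic=bic,
        n_obs=int(arrays.N),
        n_params=n_params,
        converged=converged,
        predictions=predictions,
        nll_trace=np.asarray(obj.trace),
    )


def fit_metrics(fit: FitResult, cohort: Cohort | None = None):
    """Recompute (mse, r2, nll, aic, bic) from the stored residuals and
    the reported parameter count; must agree with the fitter's values."""
    y = fit.predictions["y_obs"].to_numpy()
    pred = fit.predictions["y_pred"].to_numpy()
    resid = y - pred
    mse = float(np.mean(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        warnings.warn("R^2 undefined for a zero-variance response")
        r2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sst
    aic = 2.0 * fit.n_params + 2.0 * fit.nll
    bic = fit.n_params * math.log(fit.n_obs) + 2.0 * fit.nll
    return mse, r2, fit.nll, aic, bic


def default_model_suite(p_r: float = 1.0) -> list:
    """Fitting specs for the four standard candidate laws (initial
    values are refined by the data-driven heuristics inside the fit)."""
    return [
        NmemSpec(GrowthLawSpec("exponential", {"a": 1e-3}, p_r)),
        NmemSpec(GrowthLawSpec("gompertz", {"a": 1e-3, "K": 100.0}, p_r)),
        NmemSpec(GrowthLawSpec("logistic", {"a": 1e-3, "K": 100.0}, p_r)),
        NmemSpec(GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5}, p_r)),
    ]


def model_selection(cohort: Cohort, specs, **overrides) -> pd.DataFrame:
    """Fit every candidate law and rank by AIC (ties: BIC, then fewer
    parameters).  Failed fits are recorded, not fatal."""
    rows = []
    for spec in specs:
        if overrides:
            spec = replace(spec, **overrides)
        try:
            fit = fit_nmem(cohort, spec)
            rows.append(
                {
                    "model": spec.law.name,
                    "n_params": fit.n_params,
                    "mse": fit.mse,
                    "r2": fit.r2,
                    "nll": fit.nll,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "converged": fit.converged,
                }
            )
        except Exception as exc:  # noqa: BLE001 — record, don't abort the comparison
            rows.append(
                {
                    "model": spec.law.name,
                    "n_params": math.nan,
                    "mse": math.nan,
                    "r2": math.nan,
                    "nll": math.nan,
                    "aic": math.inf,
                    "bic": math.inf,
                    "converged": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(["aic", "bic", "n_params"], kind="mergesort").reset_index(
        drop=True
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
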