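"""Three-step Aurora B -> NDC80 phosphorylation -> binding model.

Aurora B autoactivates in trans within two independent pools (haspin-
dependent and haspin-independent), giving a piecewise-linear steady-state
active concentration

    [A_active] = A* - K            for [A] <  A*
               = [A] - K           for [A] >= A*,

with K the combined activation equilibrium constant and A* the threshold
concentration above which activity grows with concentration.  Active Aurora B
sets the steady-state phosphorylated fraction of the Hec1 tail sites,
``f_phos = (1 + Kphos/[A_active])^-1``, and phosphorylation weakens binding
through a linearized equilibrium constant, ``f_bound = (1 + K0 +
K0'*f_phos)^-1``.  This module provides the closed forms, the weighted
least-squares fits used to calibrate them, the sensor and intensity
calibration maps, exponential drug-response time-course fits, and an ODE
integrator that serves as an independent steady-state oracle for the closed
forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "AuroraActivationParams",
    "PhosBindingParams",
    "SensorCalibration",
    "IntensityCalibration",
    "ExpFitResult",
    "UnidentifiableError",
    "active_aurora",
    "phos_fraction",
    "binding_fraction",
    "binding_from_concentration",
    "fit_phos_binding",
    "fit_conc_binding",
    "sensor_to_phos",
    "incenp_to_concentration",
    "predict_binding_vs_kk",
    "fit_exp_timecourse",
    "ode_steady_state_oracle",
]


class UnidentifiableError(ValueError):
    """The requested parameters cannot be determined from the data."""


@dataclass(frozen=True)
class AuroraActivationParams:
    """K (uM): combined activation equilibrium constant Khd + Khi.
    A_star (uM): threshold Aurora B concentration Khd + [Ahi]."""

    K: float
    A_star: float

    def __post_init__(self) -> None:
        if self.A_star < self.K:
            raise ValueError("A_star must be >= K (active level would be negative)")


@dataclass(frozen=True)
class PhosBindingParams:
    """Kphos (uM): NDC80 phosphorylation equilibrium constant.
    K0, K0_prime: linearized binding equilibrium Kbinding = K0 + K0'*f_phos."""

    Kphos: float
    K0: float
    K0_prime: float

    def __post_init__(self) -> None:
        if self.Kphos <= 0 or self.K0 <= 0 or self.K0_prime < 0:
            raise ValueError("require Kphos > 0, K0 > 0, K0_prime >= 0")


@dataclass(frozen=True)
class SensorCalibration:
    """Anchor points of the linear kinase-sensor -> phosphorylation map."""

    f_sensor_WT: float = 0.540
    f_sensor_ZM: float = 0.368
    f_phos_WT: float = 1.0 / 9.0
    f_phos_ZM: float = 0.0

    def __post_init__(self) -> None:
        if self.f_sensor_WT <= self.f_sensor_ZM:
            raise ValueError("degenerate calibration: f_sensor_WT must exceed f_sensor_ZM")


@dataclass(frozen=True)
class IntensityCalibration:
    """Map from inner-centromere-normalized INCENP intensity to Aurora B
    concentration; the pre-treatment mid-centromere intensity corresponds to
    the 10 uM peak concentration."""

    I_mid_bar: float
    I_bg: float
    peak_conc: float = 10.0

    def __post_init__(self) -> None:
        if self.I_mid_bar <= self.I_bg:
            raise ValueError("I_mid_bar must exceed I_bg")


@dataclass(frozen=True)
class ExpFitResult:
    A: float
    tau: float
    c: float
    ci95: dict[str, tuple[float, float]]
    se: dict[str, float]

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def active_aurora(A_total: float, p: AuroraActivationParams) -> float:
    """Steady-state active Aurora B concentration (uM), piecewise in [A]."""
    A_total = float(A_total)
    if A_total < 0:
        raise ValueError("A_total must be nonnegative")
    return (p.A_star - p.K) if A_total < p.A_star else (A_total - p.K)


def phos_fraction(A_active: float, Kphos: float) -> float:
    """Fraction of phosphorylated Hec1 tail sites at a given kinase level."""
    if A_active <= 0:
        raise ValueError("A_active must be positive")
    if Kphos <= 0:
        raise ValueError("Kphos must be positive")
    return 1.0 / (1.0 + Kphos / A_active)


def binding_fraction(f_phos: float, p: PhosBindingParams) -> float:
    """NDC80-kMT bound fraction at a given phosphorylation level."""
    if not (0.0 <= f_phos <= 1.0):
        raise ValueError("f_phos must lie in [0, 1]")
    return 1.0 / (1.0 + p.K0 + p.K0_prime * f_phos)


def binding_from_concentration(
    A_total: float, aur: AuroraActivationParams, pb: PhosBindingParams
) -> float:
    """Composition of the three steps: f_bound as a function of total [A].

    Constant at the plateau value below the activation threshold A*, strictly
    decreasing above it.
    """
    return binding_fraction(phos_fraction(active_aurora(A_total, aur), pb.Kphos), pb)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def _wls_ci(res, n_params: int, names: Sequence[str]):
    """SEs and 95% CIs from the least-squares Jacobian (linearized)."""
    dof = max(res.fun.size - n_params, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
        cov = np.full((n_params, n_params), np.nan)
    from scipy.stats import t as tdist

    tq = tdist.ppf(0.975, dof)
    ci = {nm: (res.x[i] - tq * se[i], res.x[i] + tq * se[i]) for i, nm in enumerate(names)}
    return se, ci, cov, tq


def fit_phos_binding(
    data: pd.DataFrame | np.ndarray,
) -> tuple[PhosBindingParams, dict[str, float], dict[str, tuple[float, float]]]:
    """Fit K0 and K0' of ``f_bound = (1 + K0 + K0'*f_phos)^-1``.

    ``data`` holds columns/rows (f_phos, f_bound[, sem]); points are weighted
    by inverse squared SEM when provided.  Returns (params, se, ci95) with a
    placeholder Kphos of 1 in the params (not fit here).
    """
    arr = np.asarray(data, dtype=float)
    if isinstance(data, pd.DataFrame):
        fp = data["f_phos"].to_numpy(float)
        fb = data["f_bound"].to_numpy(float)
        sem = data["sem"].to_numpy(float) if "sem" in data else np.ones_like(fp)
    else:
        fp, fb = arr[:, 0], arr[:, 1]
        sem = arr[:, 2] if arr.shape[1] > 2 else np.ones_like(fp)
    if fp.size < 3 or np.unique(fp).size < 2:
        raise UnidentifiableError("need >= 3 points with distinct f_phos to fit K0'")

    def resid(x):
        K0, K0p = x
        return (1.0 / (1.0 + K0 + K0p * fp) - fb) / sem

    res = least_squares(resid, x0=np.array([1.0, 10.0]),
                        bounds=([1e-9, 0.0], [np.inf, np.inf]))
    se, ci, _, _ = _wls_ci(res, 2, ["K0", "K0_prime"])
    params = PhosBindingParams(Kphos=1.0, K0=float(res.x[0]), K0_prime=float(res.x[1]))
    return params, {"K0": float(se[0]), "K0_prime": float(se[1])}, ci


def fit_conc_binding(
    data: pd.DataFrame | np.ndarray,
    fixed: PhosBindingParams,
) -> tuple[AuroraActivationParams, float, dict[str, float], dict[str, tuple[float, float]]]:
    """Fit (K, Kphos, A*) of the concentration-binding relation.

    ``data`` holds (aurora_uM, f_bound[, sem]); K0 and K0' are taken from
    ``fixed``.  The constraint A* >= K is enforced by fitting dA = A* - K >= 0;
    the SE of A* follows by the delta method.  Raises
    :class:`UnidentifiableError` when the data do not straddle the plateau
    break (all points on one branch of the piecewise relation).
    """
    if isinstance(data, pd.DataFrame):
        conc = data.iloc[:, 0].to_numpy(float)
        fb = data.iloc[:, 1].to_numpy(float)
        sem = data["sem"].to_numpy(float) if "sem" in data else np.ones_like(conc)
    else:
        arr = np.asarray(data, dtype=float)
        conc, fb = arr[:, 0], arr[:, 1]
        sem = arr[:, 2] if arr.shape[1] > 2 else np.ones_like(conc)

    def model(x, a):
        K, dA, Kphos = x
        aur = AuroraActivationParams(K=K, A_star=K + dA)
        pb = PhosBindingParams(Kphos=Kphos, K0=fixed.K0, K0_prime=fixed.K0_prime)
        return np.array([binding_from_concentration(ai, aur, pb) for ai in a])

    def resid(x):
        return (model(x, conc) - fb) / sem

    res = least_squares(resid, x0=np.array([2.0, 2.0, 10.0]),
                        bounds=([1e-6, 1e-6, 1e-6], [np.inf, np.inf, np.inf]))
    K, dA, Kphos = res.x
    A_star = K + dA
    if A_star >= conc.max() - 1e-9:
        raise UnidentifiableError(
            "all data lie below the activation threshold (plateau only)")
    if A_star <= conc.min() + 1e-9:
        raise UnidentifiableError(
            "all data lie above the activation threshold; K and A* degenerate")
    se, ci, cov, tq = _wls_ci(res, 3, ["K", "dA", "Kphos"])

    # The piecewise break makes the linearized variance of A* unreliable;
    # profile the residual sum of squares over A* instead (F criterion).
    dof = max(conc.size - 3, 1)
    ssr_min = 2 * res.cost
    ssr_crit = ssr_min * (1.0 + tq**2 / dof)

    def ssr_profile(a_star: float) -> float:
        def resid_fixed(x):
            Kf, Kphosf = x
            aur = AuroraActivationParams(K=Kf, A_star=a_star)
            pbf = PhosBindingParams(Kphos=Kphosf, K0=fixed.K0,
                                    K0_prime=fixed.K0_prime)
            pred = np.array([binding_from_concentration(ai, aur, pbf)
                             for ai in conc])
            return (pred - fb) / sem

        r = least_squares(resid_fixed, x0=np.array([min(K, a_star - 1e-6), Kphos]),
                          bounds=([1e-6, 1e-6], [a_star, np.inf]))
        return 2 * r.cost

    from scipy.optimize import brentq

    def ci_edge(outer: float) -> float:
        if ssr_profile(outer) < ssr_crit:  # CI extends past the search range
            return outer
        a, b = sorted((outer, A_star))
        return brentq(lambda x: ssr_profile(x) - ssr_crit, a, b, xtol=1e-4)

    lo = ci_edge(max(conc.min(), 0.3 * A_star))
    hi = ci_edge(min(conc.max(), 3.0 * A_star))
    se_astar = float((hi - lo) / (2 * tq)) if np.isfinite(lo) and np.isfinite(hi) \
        else np.nan
    se_out = {"K": float(se[0]), "Kphos": float(se[2]), "A_star": se_astar}
    ci_out = {
        "K": tuple(map(float, ci["K"])),
        "Kphos": tuple(map(float, ci["Kphos"])),
        "A_star": (float(lo), float(hi)),
    }
    return (AuroraActivationParams(K=float(K), A_star=float(A_star)),
            float(Kphos), se_out, ci_out)


# ---------------------------------------------------------------------------
# Calibration maps
# ---------------------------------------------------------------------------


def sensor_to_phos(f_sensor: float, cal: SensorCalibration | None = None) -> float:
    """Linear two-anchor map from kinase-sensor non-FRET fraction to f_phos.

    Anchors: the pre-inhibition steady state maps to f_phos = 1/9 and the
    fully inhibited state to 0.  Extrapolation below 0 is clipped with a
    warning.
    """
    cal = cal or SensorCalibration()
    f_phos = (
        (f_sensor - cal.f_sensor_ZM) / (cal.f_sensor_WT - cal.f_sensor_ZM)
    ) * (cal.f_phos_WT - cal.f_phos_ZM) + cal.f_phos_ZM
    if f_phos < 0:
        warnings.warn("sensor value maps below 0 phosphorylation; clipped",
                      RuntimeWarning)
        f_phos = 0.0
    return float(f_phos)


def incenp_to_concentration(
    I_ndc80: float, cal: IntensityCalibration
) -> tuple[float, float]:
    """Normalized INCENP intensity at NDC80 and the Aurora B concentration.

    ``norm = (I - I_bg) / (I_mid_bar - I_bg)``; the concentration is
    ``norm * peak_conc`` (10 uM at the inner-centromere peak).  Negative
    normalized intensities are clipped to 0 with a warning.
    """
    norm = (I_ndc80 - cal.I_bg) / (cal.I_mid_bar - cal.I_bg)
    if norm < 0:
        warnings.warn("intensity below background; clipped to 0", RuntimeWarning)
        norm = 0.0
    return float(norm), float(norm * cal.peak_conc)


def predict_binding_vs_kk(
    intensity_line: tuple[float, float],
    aur: AuroraActivationParams,
    pb: PhosBindingParams,
    dkk_grid: Sequence[float],
) -> pd.DataFrame:
    """Predicted binding fraction over a K-K distance grid.

    ``intensity_line`` is the (slope, intercept) of the measured linear
    Aurora B concentration vs K-K distance relation (uM/um, uM).
    """
    slope, intercept = intensity_line
    dkk = np.asarray(dkk_grid, dtype=float)
    conc = np.clip(slope * dkk + intercept, 0.0, None)
    fb = np.array([binding_from_concentration(a, aur, pb) for a in conc])
    return pd.DataFrame({"dkk_um": dkk, "aurora_uM": conc, "f_bound": fb})


# ---------------------------------------------------------------------------
# Time-course fits
# ---------------------------------------------------------------------------


def fit_exp_timecourse(
    tc: pd.DataFrame | np.ndarray,
    kind: str,
    sem: np.ndarray | None = None,
) -> ExpFitResult:
    """Fit an exponential drug-response time course with an onset indicator.

    ``rising``:  y = A (1 - exp(-I(t>=0) t/tau)) + c
    ``decaying``: y = A exp(-I(t>=0) t/tau) + c
    Weighted (inverse squared SEM) nonlinear least squares; 95% CIs from the
    linearized covariance.
    """
    if kind not in ("rising", "decaying"):
        raise ValueError("kind must be 'rising' or 'decaying'")
    if isinstance(tc, pd.DataFrame):
        t = tc.iloc[:, 0].to_numpy(float)
        y = tc.iloc[:, 1].to_numpy(float)
    else:
        arr = np.asarray(tc, dtype=float)
        t, y = arr[:, 0], arr[:, 1]
    if not (np.any(t < 0) and np.any(t > 0)):
        raise ValueError("time course must include pre- and post-onset samples")
    w = np.ones_like(t) if sem is None else 1.0 / np.asarray(sem, dtype=float)
    ind = (t >= 0).astype(float)

    def model(x):
        A, tau, c = x
        e = np.exp(-ind * t / tau)
        return (A * (1 - e) + c) if kind == "rising" else (A * e + c)

    span = y.max() - y.min()
    x0 = np.array([max(span, 1e-3), max(t.max() / 3, 1e-2), y[t < 0].mean()])
    res = least_squares(lambda x: (model(x) - y) * w, x0=x0,
                        bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]))
    if res.x[1] <= 2e-6 or res.x[1] >= t.max() * 100:
        warnings.warn("tau hit a bound; time constant unreliable", RuntimeWarning)
    se, ci, _, _ = _wls_ci(res, 3, ["A", "tau", "c"])
    return ExpFitResult(A=float(res.x[0]), tau=float(res.x[1]), c=float(res.x[2]),
                        ci95={k: (float(v[0]), float(v[1])) for k, v in ci.items()},
                        se={nm: float(s) for nm, s in zip(["A", "tau", "c"], se)})


# ---------------------------------------------------------------------------
# ODE oracle
# ---------------------------------------------------------------------------


def ode_steady_state_oracle(
    pool_rates: Sequence[tuple[float, float]],
    pool_totals: Sequence[float],
    kp: float,
    kdp: float,
    kon: float,
    koff0: float,
    koff_prime: float = 0.0,
    t_end: float = 1e4,
    tol: float = 1e-9,
) -> tuple[float, float, float]:
    """Integrate the full kinetic chain to steady state.

    Per pool x: d[Ax_active]/dt = ka*[Ax_active]*([Ax]-[Ax_active]) -
    kd*[Ax_active].  Phosphorylation: df/dt = kp*[A_active]*(1-f) - kdp*f.
    Binding: db/dt = kon*(1-b) - (koff0 + koff_prime*f)*kon*b, i.e. the
    unbinding equilibrium constant is K0 + K0'*f with K0 = koff0 and
    K0' = koff_prime when rates are expressed relative to kon.

    Returns (A_active, f_phos, f_bound) at steady state; raises if the
    integration does not settle within ``t_end``.
    """
    if any(ka <= 0 or kd <= 0 for ka, kd in pool_rates):
        raise ValueError("rates must be positive")
    n_pools = len(pool_rates)

    def rhs(_t, yv):
        act = yv[:n_pools]
        f, b = yv[n_pools], yv[n_pools + 1]
        d_act = [
            ka * a * (tot - a) - kd * a
            for (ka, kd), tot, a in zip(pool_rates, pool_totals, act)
        ]
        A_active = max(act.sum(), 0.0)
        df = kp * A_active * (1 - f) - kdp * f
        db = kon * (1 - b) - (koff0 + koff_prime * f) * kon * b
        return [*d_act, df, db]

    y = np.array([0.9 * tot for tot in pool_totals] + [0.5, 0.5])
    t_done = 0.0
    step = 50.0
    while t_done < t_end:
        sol = solve_ivp(rhs, (0.0, step), y, method="LSODA", rtol=1e-10, atol=1e-12)
        y_new = sol.y[:, -1]
        scale = max(float(np.max(np.abs(y_new))), 1.0)
        if np.max(np.abs(y_new - y)) / scale < tol:
            y = y_new
            break
        y = y_new
        t_done += step
    else:
        raise RuntimeError("ODE did not reach steady state within t_end")
    A_active = float(np.sum(np.clip(y[:n_pools], 0.0, None)))
    return A_active, float(y[n_pools]), float(y[n_pools + 1])
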