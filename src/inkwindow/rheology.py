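"""Ink rheology: Cross-model flow-curve fitting and oscillatory-sweep analysis.

Extrusion inks are characterized by a rotational shear-rate sweep (viscosity
``eta`` vs shear rate ``gamma_dot``) and an oscillatory stress sweep (storage
and loss moduli ``G'``, ``G''`` vs oscillation stress).  This module fits the
four-parameter Cross law

    eta(gamma_dot) = eta_inf + (eta_0 - eta_inf) / (1 + (k * gamma_dot)**m)

to flow curves, truncates the high-rate tail when edge fracture corrupts it,
extracts the linear-viscoelastic (LVE) plateau moduli, and locates the yield
onset as the intersection of tangents fitted before and after yielding, the
construction used by rheometer software.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FlowCurve",
    "OscSweep",
    "CrossFit",
    "LVEPlateau",
    "ViscoSummary",
    "RheologyError",
    "cross_viscosity",
    "truncate_edge_fracture",
    "fit_cross",
    "extract_lve",
    "detect_yield_onset",
    "summarize_visco",
]


class RheologyError(ValueError):
    """Raised for degenerate sweeps: too few points, no plateau, no onset."""


def _as_positive_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be finite and strictly positive")
    return arr


@dataclass(frozen=True)
class FlowCurve:
    """A rotational shear-rate sweep: viscosity (Pa·s) vs shear rate (1/s)."""

    shear_rate: np.ndarray
    viscosity: np.ndarray
    temperature_C: float = 25.0

    def __post_init__(self):
        sr = _as_positive_array(self.shear_rate, "shear_rate")
        visc = _as_positive_array(self.viscosity, "viscosity")
        if sr.size != visc.size:
            raise ValueError("shear_rate and viscosity must have equal length")
        if sr.size < 4:
            raise ValueError("flow curve needs at least 4 points")
        if np.any(np.diff(sr) <= 0):
            raise ValueError("shear_rate must be strictly increasing")
        object.__setattr__(self, "shear_rate", sr)
        object.__setattr__(self, "viscosity", visc)

    def __len__(self) -> int:
        return self.shear_rate.size


@dataclass(frozen=True)
class OscSweep:
    """An oscillatory stress sweep: G' and G'' (Pa) vs applied stress (Pa)."""

    stress: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray

    def __post_init__(self):
        stress = _as_positive_array(self.stress, "stress")
        gp = _as_positive_array(self.g_prime, "g_prime")
        gpp = _as_positive_array(self.g_double_prime, "g_double_prime")
        if not (stress.size == gp.size == gpp.size):
            raise ValueError("sweep arrays must have equal length")
        if stress.size < 6:
            raise ValueError("oscillatory sweep needs at least 6 points")
        if np.any(np.diff(stress) <= 0):
            raise ValueError("stress must be strictly increasing")
        object.__setattr__(self, "stress", stress)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_double_prime", gpp)

    def __len__(self) -> int:
        return self.stress.size


@dataclass(frozen=True)
class CrossFit:
    """Cross-model parameters with fit diagnostics.

    ``n = 1 - m`` is the shear-thinning index of the equivalent power law.
    ``r2`` is computed on log-viscosity.  ``covariance`` is the 4x4
    linearized parameter covariance in the order (eta0, eta_inf, k, m); the
    eta_inf row/column is zero when the fit pinned eta_inf to 0.
    """

    eta0: float
    eta_inf: float
    k: float
    m: float
    r2: float
    covariance: np.ndarray
    unidentifiable_m: bool = False

    @property
    def shear_thinning_index_n(self) -> float:
        return 1.0 - self.m

    def predict(self, shear_rate) -> np.ndarray:
        return cross_viscosity(shear_rate, self.eta0, self.eta_inf, self.k, self.m)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariance"] = np.asarray(self.covariance).tolist()
        d["shear_thinning_index_n"] = self.shear_thinning_index_n
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class LVEPlateau:
    """Plateau moduli over the detected LVE run; iterable as (G', G'')."""

    g_prime_lve: float
    g_double_prime_lve: float
    run_indices: tuple = field(default=(), compare=False)

    def __iter__(self):
        return iter((self.g_prime_lve, self.g_double_prime_lve))


@dataclass(frozen=True)
class ViscoSummary:
    """LVE moduli and yield onset of one oscillatory sweep."""

    g_prime_lve: float
    g_double_prime_lve: float
    tau_y: float
    lve_end_index: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cross_viscosity(shear_rate, eta0: float, eta_inf: float, k: float, m: float):
    """Evaluate the Cross law at the given shear rates."""
    gd = np.asarray(shear_rate, dtype=float)
    return eta_inf + (eta0 - eta_inf) / (1.0 + (k * gd) ** m)


# --------------------------------------------------------------------------
# edge-fracture truncation


def _loglog_slopes(curve: FlowCurve) -> np.ndarray:
    """Backward-difference slope d(log eta)/d(log gamma_dot) at points 1..n-1."""
    lg = np.log(curve.shear_rate)
    le = np.log(curve.viscosity)
    return np.diff(le) / np.diff(lg)


def truncate_edge_fracture(
    curve: FlowCurve, cutoff: float | str = "auto", slope_delta: float = 0.1
) -> FlowCurve:
    """Drop the high-rate tail of a flow curve corrupted by edge fracture.

    A Cross fluid's log-log slope is bounded below by ``-m >= -1``; a slope
    steeper than ``-(1 + slope_delta)`` therefore signals sample loss from
    the rheometer gap rather than real thinning.  With ``cutoff='auto'`` the
    cut is placed at the first rate whose local (backward-difference) slope
    drops below that threshold; an explicit ``cutoff`` removes all points at
    rates >= cutoff.  Idempotent: a truncated curve truncates to itself.
    """
    if cutoff == "auto":
        slopes = _loglog_slopes(curve)
        bad = np.nonzero(slopes < -(1.0 + slope_delta))[0]
        if bad.size == 0:
            return curve
        cut_rate = curve.shear_rate[bad[0] + 1]
    else:
        cut_rate = float(cutoff)
        if cut_rate <= curve.shear_rate[0]:
            raise ValueError("cutoff must exceed the lowest shear rate")
    keep = curve.shear_rate < cut_rate
    if keep.sum() < 4:
        raise RheologyError("curve too short after truncation")
    return FlowCurve(
        curve.shear_rate[keep], curve.viscosity[keep], curve.temperature_C
    )


# --------------------------------------------------------------------------
# Cross fit

_NEWTONIAN_LOG_SPAN = 0.01  # max decade-spread of log eta treated as constant


def fit_cross(
    curve: FlowCurve,
    fix_eta_inf_zero: bool = False,
    m_starts: tuple = (0.3, 0.6, 0.9),
) -> CrossFit:
    """Least-squares Cross fit minimizing squared log-viscosity residuals.

    The fit is performed in log space because viscosities span decades and a
    raw-space fit would be dominated by the low-rate plateau.  Multi-start
    over ``m_starts`` guards against the local minima of the (k, m) coupling.
    With ``fix_eta_inf_zero`` the infinite-rate plateau is pinned to zero
    (appropriate when the sweep never approaches it).
    """
    gd = curve.shear_rate
    log_eta = np.log(curve.viscosity)

    if np.ptp(log_eta) < _NEWTONIAN_LOG_SPAN:
        # Newtonian limit: eta0 identified, (k, m) are not.
        eta0 = float(np.exp(log_eta.mean()))
        cov = np.zeros((4, 4))
        return CrossFit(eta0, 0.0, 0.0, 0.0, r2=1.0, covariance=cov,
                        unidentifiable_m=True)

    eta_max = float(curve.viscosity.max())
    eta_min = float(curve.viscosity.min())

    # k init: inverse of the rate where viscosity has dropped half a decade
    half_drop = eta_max / np.sqrt(10.0)
    below = np.nonzero(curve.viscosity <= half_drop)[0]
    k0 = 1.0 / gd[below[0]] if below.size else 1.0 / np.sqrt(gd[0] * gd[-1])

    def residuals(theta):
        if fix_eta_inf_zero:
            eta0, k, m = theta
            eta_inf = 0.0
        else:
            eta0, eta_inf, k, m = theta
        model = cross_viscosity(gd, eta0, eta_inf, k, m)
        return np.log(np.maximum(model, 1e-300)) - log_eta

    if fix_eta_inf_zero:
        lower = [eta_min * 1e-3, 1e-12, 0.0]
        upper = [eta_max * 1e3, 1e9, 1.0]
    else:
        lower = [eta_min * 1e-3, 0.0, 1e-12, 0.0]
        upper = [eta_max * 1e3, eta_max, 1e9, 1.0]

    best = None
    for m0 in m_starts:
        if fix_eta_inf_zero:
            x0 = [eta_max, k0, m0]
        else:
            x0 = [eta_max, eta_min * 0.1, k0, m0]
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # numerical failure on one start is tolerable
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RheologyError("Cross fit failed to converge from all starts")

    if fix_eta_inf_zero:
        eta0, k, m = best.x
        eta_inf = 0.0
    else:
        eta0, eta_inf, k, m = best.x

    res = best.fun
    ss_res = float(res @ res)
    ss_tot = float(((log_eta - log_eta.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    dof = max(len(curve) - best.x.size, 1)
    sigma2 = ss_res / dof
    jtj = best.jac.T @ best.jac
    cov_small = sigma2 * np.linalg.pinv(jtj)
    cov = np.zeros((4, 4))
    if fix_eta_inf_zero:
        idx = np.array([0, 2, 3])
        cov[np.ix_(idx, idx)] = cov_small
    else:
        cov = cov_small

    return CrossFit(float(eta0), float(eta_inf), float(k), float(m),
                    r2=r2, covariance=cov)


# --------------------------------------------------------------------------
# oscillatory sweep analysis


def _plateau_run(values: np.ndarray, tol: float) -> int:
    """Length of the initial run staying within ``tol`` of the low-stress
    median.

    The reference is the median of the first few points; the run ends at the
    first decisive departure — a point beyond 1.5x the tolerance, or two
    consecutive points outside it.  An isolated mild outlier (measurement
    noise) does not terminate the plateau.
    """
    n = values.size
    ref = float(np.median(values[:max(3, n // 8)]))
    dev = np.abs(values / ref - 1.0)
    run = 0
    for i in range(n):
        if dev[i] > tol:
            decisive = (dev[i] > 1.5 * tol or i + 1 >= n or dev[i + 1] > tol)
            if decisive:
                break
        run = i + 1
    return run


def extract_lve(osc: OscSweep, plateau_tol: float = 0.05) -> LVEPlateau:
    """Mean plateau moduli over the initial linear-viscoelastic run.

    The LVE run is the longest initial stretch where both G' and G'' stay
    within ``plateau_tol`` (fractional) of their low-stress medians.  Raises
    :class:`RheologyError` when no run of at least 3 points exists.
    """
    run = min(_plateau_run(osc.g_prime, plateau_tol),
              _plateau_run(osc.g_double_prime, plateau_tol))
    if run < 3:
        raise RheologyError("no LVE plateau")
    idx = tuple(range(run))
    return LVEPlateau(
        float(osc.g_prime[:run].mean()),
        float(osc.g_double_prime[:run].mean()),
        run_indices=idx,
    )


def detect_yield_onset(
    osc: OscSweep, plateau_tol: float = 0.05, buffer_frac: float = 0.10
) -> float:
    """Yield-onset stress from the intersection of log-log tangents of G'.

    One line is fitted to the LVE plateau of G' and one to the post-yield
    decay (points past the plateau, skipping a transition buffer of
    ``buffer_frac`` of the sweep length); the onset is the stress where the
    two lines intersect.  Being a log-log construction, rescaling stress by a
    factor c rescales the onset by exactly c.
    """
    n = len(osc)
    run = _plateau_run(osc.g_prime, plateau_tol)
    if run < 3:
        raise RheologyError("onset undetectable: no G' plateau")
    # transition buffer, shrunk if the decay region is short (a high tau_y
    # leaves few post-yield points in a bounded stress ramp)
    buffer_n = max(int(round(buffer_frac * n)), 0)
    buffer_n = min(buffer_n, max(n - run - 2, 0))
    decay_start = run + buffer_n
    if n - decay_start < 2:
        raise RheologyError("onset undetectable: no post-yield decay region")

    ls = np.log(osc.stress)
    lg = np.log(osc.g_prime)
    s1, b1 = np.polyfit(ls[:run], lg[:run], 1)
    s2, b2 = np.polyfit(ls[decay_start:], lg[decay_start:], 1)
    if abs(s1 - s2) < 1e-10:
        raise RheologyError("onset undetectable: tangents are parallel")
    x_star = (b2 - b1) / (s1 - s2)
    tau_y = float(np.exp(x_star))
    if not (osc.stress[0] <= tau_y <= osc.stress[-1]):
        raise RheologyError("onset undetectable: intersection outside sweep range")
    return tau_y


def summarize_visco(osc: OscSweep, plateau_tol: float = 0.05) -> ViscoSummary:
    """LVE moduli and yield onset in one record."""
    lve = extract_lve(osc, plateau_tol)
    tau_y = detect_yield_onset(osc, plateau_tol)
    return ViscoSummary(
        g_prime_lve=lve.g_prime_lve,
        g_double_prime_lve=lve.g_double_prime_lve,
        tau_y=tau_y,
        lve_end_index=len(lve.run_indices) - 1,
    )
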