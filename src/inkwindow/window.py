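"""Dynamic printability window and desirability optimization.

The printability window is the region of (composition, pressure) space where
the fitted surfaces predict a positive gravimetric flow (Qm > 0, the ink
extrudes) and a spreading ratio below a threshold (SR < 6 by default, the
print retains accuracy).  The window can be projected onto the rheology
surfaces to read off the band of rheological properties an ink must have to
be printable at given settings.  Inside the window, an operating optimum is
located with Derringer-Suich desirability ramps: the printability index Pr is
put on target (T = 1) and SR minimized; the overall desirability is the
geometric mean of the per-yield scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .response_surface import FACTOR_COLUMNS, FittedSurface

__all__ = [
    "FactorGrid",
    "WindowResult",
    "YieldSpec",
    "DesirabilityConfig",
    "OptimumResult",
    "desirability_min",
    "desirability_target",
    "overall_desirability",
    "printability_window",
    "map_window_to_rheology",
    "optimize_desirability",
]


@dataclass(frozen=True)
class FactorGrid:
    """Cartesian evaluation grid over factors (axes strictly increasing)."""

    axes: dict  # factor letter -> sorted 1-D array

    def __post_init__(self):
        clean = {}
        for f, ax in self.axes.items():
            arr = np.asarray(ax, dtype=float)
            if arr.ndim != 1 or arr.size < 2 or np.any(np.diff(arr) <= 0):
                raise ValueError(
                    f"axis {f} must be 1-D, >= 2 points, strictly increasing")
            clean[f] = arr
        object.__setattr__(self, "axes", clean)

    @classmethod
    def from_ranges(cls, ranges: dict, resolution: int = 25) -> "FactorGrid":
        return cls({f: np.linspace(lo, hi, resolution)
                    for f, (lo, hi) in ranges.items()})

    @property
    def factors(self) -> tuple:
        return tuple(self.axes)

    @property
    def shape(self) -> tuple:
        return tuple(len(self.axes[f]) for f in self.factors)

    def points(self) -> pd.DataFrame:
        """All grid cells as rows, row-major in factor order."""
        combos = itertools.product(*(self.axes[f] for f in self.factors))
        df = pd.DataFrame(combos, columns=list(self.factors))
        return df.rename(columns=FACTOR_COLUMNS)


@dataclass(frozen=True)
class WindowResult:
    """Boolean printable region over a factor grid plus model predictions."""

    grid: FactorGrid
    printable: np.ndarray  # flat, row-major over grid.points()
    qm_hat: np.ndarray
    sr_hat: np.ndarray
    sr_threshold: float
    empty: bool
    rheology_bands: dict = field(default_factory=dict)

    def printable_points(self) -> pd.DataFrame:
        return self.grid.points()[self.printable]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.points()
        df["Qm_hat"] = self.qm_hat
        df["SR_hat"] = self.sr_hat
        df["printable"] = self.printable
        return df


@dataclass(frozen=True)
class YieldSpec:
    """Desirability shape for one yield: minimize or target mode.

    ``L``/``U`` default to the yield's min/max predictions over the printable
    region; ``T`` is required in target mode.
    """

    mode: str  # "minimize" | "target"
    L: float | None = None
    U: float | None = None
    T: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.mode not in ("minimize", "target"):
            raise ValueError("mode must be 'minimize' or 'target'")
        if self.mode == "target" and self.T is None:
            raise ValueError("target mode requires T")
        if self.L is not None and self.U is not None and not self.L < self.U:
            raise ValueError("need L < U")


@dataclass(frozen=True)
class DesirabilityConfig:
    """Per-yield desirability specs; defaults: Pr on target 1, SR minimized."""

    yields: dict = field(default_factory=lambda: {
        "Pr": YieldSpec(mode="target", T=1.0),
        "SR": YieldSpec(mode="minimize"),
    })


@dataclass(frozen=True)
class OptimumResult:
    """Best printable operating point by overall desirability."""

    point: dict  # factor letter -> value (refined)
    desirability: float
    grid_point: dict
    grid_desirability: float
    no_desirable_region: bool = False


# --------------------------------------------------------------------------
# desirability ramps (Derringer-Suich, weight w)


def desirability_min(y, L: float, U: float, w: float = 1.0):
    """Minimization ramp: 1 at y <= L, 0 at y >= U, ((U-y)/(U-L))^w between."""
    if not L < U:
        raise ValueError("need L < U")
    y = np.asarray(y, dtype=float)
    d = np.clip((U - y) / (U - L), 0.0, 1.0) ** w
    return d if d.ndim else float(d)


def desirability_target(y, L: float, T: float, U: float, w: float = 1.0):
    """Two-sided target ramp: 1 at y = T, 0 outside [L, U]."""
    if not (L <= T <= U):
        raise ValueError("need L <= T <= U")
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(T > L, (y - L) / (T - L), 1.0)
        down = np.where(U > T, (U - y) / (U - T), 1.0)
    d = np.where(y <= T, up, down)
    d = np.clip(d, 0.0, 1.0) ** w
    return d if d.ndim else float(d)


def overall_desirability(ds):
    """Geometric mean of the per-yield desirabilities."""
    ds = np.asarray(ds, dtype=float)
    if ds.size == 0:
        raise ValueError("need at least one desirability value")
    if np.any((ds < 0) | (ds > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    k = ds.shape[0]
    return np.prod(ds, axis=0) ** (1.0 / k)


# --------------------------------------------------------------------------
# window


def printability_window(
    qm_model: FittedSurface,
    sr_model: FittedSurface,
    grid: FactorGrid,
    sr_threshold: float = 6.0,
) -> WindowResult:
    """Evaluate the printable region cell by cell: Qm > 0 and SR < threshold.

    Strict inequalities on the predicted means; no interpolation — every grid
    cell is evaluated exactly.  An empty window is returned flagged, not
    raised.
    """
    pts = grid.points()
    qm = np.asarray(qm_model.predict(pts), dtype=float)
    sr = np.asarray(sr_model.predict(pts), dtype=float)
    printable = (qm > 0.0) & (sr < sr_threshold)
    return WindowResult(
        grid=grid,
        printable=printable,
        qm_hat=qm,
        sr_hat=sr,
        sr_threshold=float(sr_threshold),
        empty=not bool(printable.any()),
    )


def map_window_to_rheology(
    window: WindowResult, rheo_models: dict
) -> dict:
    """Rheological-property bands over the printable region.

    Each rheology surface (a function of composition A, B only) is evaluated
    at the printable cells' factor values; the [min, max] envelope is the
    band of that property an ink must fall in to be printable at the window's
    settings.  Empty windows yield no bands.
    """
    if window.empty:
        return {}
    pts = window.printable_points()
    bands = {}
    for name, model in rheo_models.items():
        vals = np.asarray(model.predict(pts), dtype=float)
        bands[name] = (float(vals.min()), float(vals.max()))
    return bands


# --------------------------------------------------------------------------
# desirability optimization


def _yield_bounds(spec: YieldSpec, values: np.ndarray) -> YieldSpec:
    L = spec.L if spec.L is not None else float(values.min())
    U = spec.U if spec.U is not None else float(values.max())
    scale = max(abs(L), abs(U), 1.0)
    if U - L <= scale * 1e-9:
        # (near-)constant yield over the window: widen symmetrically so the
        # ramp does not amplify float noise into an O(1) desirability spread
        pad = scale * 1e-9
        L, U = L - pad, U + pad
    T = spec.T
    if spec.mode == "target" and T is not None:
        T = min(max(T, L), U)
    return YieldSpec(spec.mode, L=L, U=U, T=T, weight=spec.weight)


def _desirability_of(spec: YieldSpec, y):
    if spec.mode == "minimize":
        return desirability_min(y, spec.L, spec.U, spec.weight)
    return desirability_target(y, spec.L, spec.T, spec.U, spec.weight)


def optimize_desirability(
    models: dict,
    config: DesirabilityConfig,
    grid: FactorGrid,
    window: WindowResult,
) -> OptimumResult:
    """Locate the printable operating point maximizing overall desirability.

    D is evaluated on the printable grid cells only; ties are broken toward
    lower pressure (factor C), then lower total polymer (A + B), then
    row-major order.  The best cell seeds a bounded Nelder-Mead refinement of
    the continuous D (zero outside the Qm/SR constraints), clipped to the
    grid's factor ranges.
    """
    if window.empty:
        return OptimumResult(point={}, desirability=0.0, grid_point={},
                             grid_desirability=0.0, no_desirable_region=True)
    pts_all = grid.points()
    pts = pts_all[window.printable]
    factors = grid.factors

    resolved = {}
    for name, spec in config.yields.items():
        vals = np.asarray(models[name].predict(pts), dtype=float)
        resolved[name] = _yield_bounds(spec, vals)

    ds = np.vstack([
        _desirability_of(resolved[name],
                         np.asarray(models[name].predict(pts), dtype=float))
        for name in config.yields
    ])
    D = overall_desirability(ds)
    if not np.any(D > 0):
        return OptimumResult(point={}, desirability=0.0, grid_point={},
                             grid_desirability=0.0, no_desirable_region=True)

    cell_vals = {f: np.asarray(pts[FACTOR_COLUMNS[f]], dtype=float)
                 for f in factors}
    pressure = cell_vals.get("C", np.zeros(D.size))
    polymer = cell_vals.get("A", 0.0) + cell_vals.get("B", 0.0)
    if np.ndim(polymer) == 0:
        polymer = np.zeros(D.size)
    # round for ranking: D differences below 1e-6 count as ties (so float
    # noise on flat surfaces cannot defeat the pressure/polymer preference);
    # the continuous refinement below restores full resolution
    order = np.lexsort((np.arange(D.size), polymer, pressure,
                        -np.round(D, 6)))
    best = order[0]
    grid_point = {f: float(cell_vals[f][best]) for f in factors}
    grid_D = float(D[best])

    bounds = [(grid.axes[f][0], grid.axes[f][-1]) for f in factors]
    qm_model = models.get("Qm")
    sr_model = models.get("SR")

    def neg_D(x):
        point = {FACTOR_COLUMNS[f]: np.array([v]) for f, v in zip(factors, x)}
        if qm_model is not None and sr_model is not None:
            qm = float(np.asarray(qm_model.predict(point))[0])
            sr = float(np.asarray(sr_model.predict(point))[0])
            if not (qm > 0.0 and sr < window.sr_threshold):
                return 0.0
        dvals = []
        for name in config.yields:
            y = float(np.asarray(models[name].predict(point))[0])
            dvals.append(_desirability_of(resolved[name], y))
        return -float(overall_desirability(np.asarray(dvals)))

    x0 = np.array([grid_point[f] for f in factors])
    res = minimize(
        lambda x: neg_D(np.clip(x, [b[0] for b in bounds],
                                [b[1] for b in bounds])),
        x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
    )
    x_ref = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    D_ref = -neg_D(x_ref)
    if D_ref < grid_D:  # refinement must never lose ground
        x_ref, D_ref = x0, grid_D
    point = {f: float(v) for f, v in zip(factors, x_ref)}
    return OptimumResult(point=point, desirability=float(D_ref),
                         grid_point=grid_point, grid_desirability=grid_D)
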