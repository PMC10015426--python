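"""Seeded generators for every input class the pipeline consumes.

Three families, all with recorded ground truth so each stage can be validated
without laboratory data:

* :func:`render_construct` — anti-aliased rasters of printed lines, angles
  and grids (dark ink on a light dish) with exact geometric metrics.
* :func:`simulate_flow_curve` / :func:`simulate_osc_sweep` — rheometer sweeps
  from known Cross-law and plateau/decay parameters, with multiplicative
  lognormal noise and an optional edge-fracture artifact.
* :func:`simulate_design` — full-factorial design tables whose responses are
  known polynomials of the factors plus Gaussian noise.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_analysis import CalibratedImage
from .response_surface import FACTOR_COLUMNS as _FACTOR_COLUMNS
from .rheology import FlowCurve, OscSweep, cross_viscosity

__all__ = [
    "EdgeNoise",
    "GridGeometry",
    "RenderSpec",
    "render_construct",
    "simulate_flow_curve",
    "simulate_osc_sweep",
    "simulate_design",
    "DEFAULT_FACTOR_LEVELS",
]


@dataclass(frozen=True)
class EdgeNoise:
    """Sinusoidal centerline wiggle of a printed line (constant width)."""

    amplitude_um: float = 0.0
    wavelength_um: float = 500.0


@dataclass(frozen=True)
class GridGeometry:
    """Printed-grid geometry: 20 x 20 mm outline at 15% infill density.

    The strand pitch follows from the infill fraction f of a rectilinear
    grid, ``2 q - q**2 = f`` with ``q = strand_width / pitch``; pores are
    rendered as rounded squares so that the pressure-driven rounding of real
    prints can be emulated via ``corner_radius_um``.
    """

    outer_mm: float = 20.0
    infill_fraction: float = 0.15
    strand_width_um: float = 300.0
    corner_radius_um: float = 0.0

    def layout(self) -> tuple[float, float, int]:
        """(pitch_um, pore_side_um, cells_per_side)."""
        if not 0 < self.infill_fraction < 1:
            raise ValueError("infill_fraction must be in (0, 1)")
        q = 1.0 - np.sqrt(1.0 - self.infill_fraction)
        pitch = self.strand_width_um / q
        n = max(int(round(self.outer_mm * 1000.0 / pitch)), 2)
        pitch = self.outer_mm * 1000.0 / n
        pore = pitch - self.strand_width_um
        if pore <= 2 * self.corner_radius_um:
            raise ValueError("corner radius too large for the pore size")
        return pitch, pore, n


@dataclass(frozen=True)
class RenderSpec:
    """Specification of one rendered construct image."""

    kind: str = "line"
    width_um: float = 500.0
    length_um: float = 5000.0
    arm_length_um: float = 4000.0
    angle_deg: float = 90.0
    tip_bulge_factor: float = 1.0
    rotation_deg: float = 0.0
    grid: GridGeometry = field(default_factory=GridGeometry)
    edge_noise: EdgeNoise = field(default_factory=EdgeNoise)
    um_per_px: float = 10.0
    supersample: int = 4
    margin_um: float = 500.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("line", "angle", "grid"):
            raise ValueError("kind must be line, angle or grid")
        if min(self.width_um, self.length_um, self.arm_length_um,
               self.um_per_px, self.margin_um) <= 0:
            raise ValueError("dimensions must be positive")
        if self.tip_bulge_factor < 1.0:
            raise ValueError("tip_bulge_factor must be >= 1")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


# --------------------------------------------------------------------------
# rasterization


def _raster(region, shape_px, spec: RenderSpec):
    """Chunked supersampled rasterization of ``region(x_um, y_um) -> bool``.

    ``region`` receives broadcastable x (row vector) and y (column vector)
    coordinate arrays in µm and must return the ink-occupancy boolean.
    """
    h, w = shape_px
    ss = spec.supersample
    step = spec.um_per_px / ss
    x = (np.arange(w * ss) + 0.5) * step
    img = np.empty((h, w), dtype=float)
    chunk = max(1, 2**22 // (w * ss))  # supersampled rows per chunk
    for r0 in range(0, h, chunk):
        r1 = min(r0 + chunk, h)
        y = ((np.arange(r0 * ss, r1 * ss) + 0.5) * step)[:, None]
        inside = region(x[None, :], y)
        cov = inside.reshape(r1 - r0, ss, w, ss).mean(axis=(1, 3))
        img[r0:r1] = 1.0 - cov  # ink dark on light field
    return img


def _dist_to_segment(x, y, p0, d, length):
    """Distance from (x, y) to the segment p0 + t*d, t in [0, length]."""
    rx, ry = x - p0[0], y - p0[1]
    t = np.clip(rx * d[0] + ry * d[1], 0.0, length)
    return np.hypot(rx - t * d[0], ry - t * d[1])


def _render_line(spec: RenderSpec):
    L, wdt = spec.length_um, spec.width_um
    a, lam = spec.edge_noise.amplitude_um, spec.edge_noise.wavelength_um
    theta = np.deg2rad(spec.rotation_deg)
    # canvas sized to hold the rotated construct
    half_diag = 0.5 * np.hypot(L, wdt + 2 * a) + spec.margin_um
    side = 2 * half_diag
    # even canvas: construct edges land on pixel boundaries, not centers
    wpx = int(np.ceil(side / spec.um_per_px))
    wpx += wpx % 2
    hpx = wpx
    cx = cy = wpx * spec.um_per_px / 2.0

    ct, st = np.cos(theta), np.sin(theta)

    def region(x, y):
        xr = (x - cx) * ct + (y - cy) * st
        yr = -(x - cx) * st + (y - cy) * ct
        offset = a * np.sin(2.0 * np.pi * (xr + L / 2.0) / lam) if a > 0 else 0.0
        return (np.abs(xr) <= L / 2.0) & (np.abs(yr - offset) <= wdt / 2.0)

    if a > 0:
        u = np.linspace(0.0, L, 20001)
        dydx = a * 2.0 * np.pi / lam * np.cos(2.0 * np.pi * u / lam)
        arc = float(np.trapezoid(np.sqrt(1.0 + dydx**2), u))
    else:
        arc = L
    perimeter = 2.0 * arc + 2.0 * wdt
    truth = {
        "t_av_um": wdt,
        "length_um": L,
        "perimeter_um": perimeter,
        "perimeter_theoretical_um": 2.0 * (L + wdt),
        "uf": perimeter / (2.0 * (L + wdt)),
    }
    return region, (hpx, wpx), truth


def _render_angle(spec: RenderSpec):
    wdt, arm = spec.width_um, spec.arm_length_um
    half = np.deg2rad(spec.angle_deg) / 2.0
    bulge_r = spec.tip_bulge_factor * wdt / 2.0
    # vertex near the left edge, bisector along +x
    extent_x = arm * np.cos(half) + wdt + bulge_r
    extent_y = 2.0 * (arm * np.sin(half) + wdt)
    wpx = int(np.ceil((extent_x + 2 * spec.margin_um) / spec.um_per_px))
    hpx = int(np.ceil((extent_y + 2 * spec.margin_um) / spec.um_per_px))
    hpx += hpx % 2
    vx = spec.margin_um + wdt + bulge_r
    vy = hpx * spec.um_per_px / 2.0
    d1 = (np.cos(half), np.sin(half))
    d2 = (np.cos(half), -np.sin(half))

    def region(x, y):
        in1 = _dist_to_segment(x, y, (vx, vy), d1, arm) <= wdt / 2.0
        in2 = _dist_to_segment(x, y, (vx, vy), d2, arm) <= wdt / 2.0
        ink = in1 | in2
        if spec.tip_bulge_factor > 1.0:
            ink |= np.hypot(x - vx, y - vy) <= bulge_r
        # constant-width turn: trim the arms' overlap wedge past the tip
        # radius, so the width along the bisector at the vertex is exactly
        # tip_bulge_factor * width (a raw capsule union would overfill the
        # inner corner: 1.5x at 60 deg even with no bulge)
        cut = in1 & in2 & (x - vx > bulge_r)
        return ink & ~cut

    truth = {
        "t_line_um": wdt,
        "t_tip_um": spec.tip_bulge_factor * wdt,
        "af": spec.tip_bulge_factor,
        "angle_deg": spec.angle_deg,
    }
    return region, (hpx, wpx), truth


def _render_grid(spec: RenderSpec):
    pitch, pore, n = spec.grid.layout()
    S = spec.grid.outer_mm * 1000.0
    r = spec.grid.corner_radius_um
    m = spec.margin_um
    side_px = int(np.ceil((S + 2 * m) / spec.um_per_px))
    h = pore / 2.0

    def region(x, y):
        gx, gy = x - m, y - m
        in_square = (gx >= 0) & (gx <= S) & (gy >= 0) & (gy <= S)
        dx = np.abs(np.mod(gx, pitch) - pitch / 2.0)
        dy = np.abs(np.mod(gy, pitch) - pitch / 2.0)
        in_pore = (dx <= h) & (dy <= h)
        if r > 0:
            ax = np.maximum(dx - (h - r), 0.0)
            ay = np.maximum(dy - (h - r), 0.0)
            in_pore &= ax**2 + ay**2 <= r**2
        return in_square & ~in_pore

    pore_perim = 4.0 * (pore - 2.0 * r) + 2.0 * np.pi * r
    pore_area = pore**2 - (4.0 - np.pi) * r**2
    truth = {
        "n_pores": n * n,
        "cells_per_side": n,
        "pitch_um": pitch,
        "pore_side_um": pore,
        "pore_perimeter_um": pore_perim,
        "pore_area_um2": pore_area,
        "pr": pore_perim**2 / (16.0 * pore_area),
    }
    return region, (side_px, side_px), truth


def render_construct(spec: RenderSpec):
    """Render one construct; returns ``(CalibratedImage, ground_truth)``.

    The ground-truth record carries the exact metric values implied by the
    geometry (closed form or quadrature) plus the pixel-center footprint
    under ``"mask"``.  With ``supersample=1`` the image is exactly two-level
    and equals the footprint; higher values give 4x-style anti-aliasing.
    """
    builders = {"line": _render_line, "angle": _render_angle,
                "grid": _render_grid}
    region, shape, truth = builders[spec.kind](spec)
    if max(shape) * spec.um_per_px > 1e6:
        raise ValueError("construct exceeds the 1 m canvas bound")
    img = _raster(region, shape, spec)

    # exact pixel-center footprint, independent of supersampling
    h, w = shape
    x = (np.arange(w) + 0.5) * spec.um_per_px
    mask = np.zeros(shape, dtype=bool)
    chunk = max(1, 2**22 // w)
    for r0 in range(0, h, chunk):
        r1 = min(r0 + chunk, h)
        y = ((np.arange(r0, r1) + 0.5) * spec.um_per_px)[:, None]
        mask[r0:r1] = region(x[None, :], y)
    truth = dict(truth, mask=mask, kind=spec.kind, um_per_px=spec.um_per_px)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)
    return CalibratedImage(img, spec.um_per_px), truth


# --------------------------------------------------------------------------
# rheometer sweeps


def simulate_flow_curve(
    eta0: float = 200.0,
    eta_inf: float = 0.0,
    k: float = 0.5,
    m: float = 0.7,
    n_points: int = 30,
    noise: float = 0.0,
    rate_range: tuple = (0.1, 300.0),
    artifact: bool = False,
    artifact_onset: float = 100.0,
    artifact_slope: float = -3.0,
    seed: int = 0,
):
    """Cross-law flow curve on log-spaced rates, optionally with noise and an
    edge-fracture artifact (extra power-law decay beyond ``artifact_onset``).

    Returns ``(FlowCurve, truth)`` where truth records the generating
    parameters and the first artifact-affected index (or None).
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    rates = np.geomspace(rate_range[0], rate_range[1], n_points)
    eta = cross_viscosity(rates, eta0, eta_inf, k, m)
    artifact_start = None
    if artifact:
        beyond = rates > artifact_onset
        eta = eta * np.where(beyond, (rates / artifact_onset) ** artifact_slope, 1.0)
        idx = np.nonzero(beyond)[0]
        artifact_start = int(idx[0]) if idx.size else None
    if noise > 0:
        rng = np.random.default_rng(seed)
        eta = eta * np.exp(rng.normal(0.0, noise, eta.shape))
    truth = {"eta0": eta0, "eta_inf": eta_inf, "k": k, "m": m,
             "artifact_start": artifact_start}
    return FlowCurve(rates, eta), truth


def simulate_osc_sweep(
    g_prime_lve: float = 250.0,
    g_double_prime_lve: float = 357.0,
    tau_y: float = 500.0,
    decay_slope: float = -2.0,
    gpp_decay_slope: float = -1.0,
    n_points: int = 40,
    noise: float = 0.0,
    stress_range: tuple = (0.1, 1000.0),
    seed: int = 0,
):
    """Oscillatory stress sweep: flat LVE plateaus up to ``tau_y`` followed by
    power-law decay of both moduli.  Returns ``(OscSweep, truth)``."""
    if n_points < 6:
        raise ValueError("need at least 6 points")
    stress = np.geomspace(stress_range[0], stress_range[1], n_points)

    def modulus(plateau, slope):
        return np.where(stress <= tau_y, plateau,
                        plateau * (stress / tau_y) ** slope)

    gp = modulus(g_prime_lve, decay_slope)
    gpp = modulus(g_double_prime_lve, gpp_decay_slope)
    if noise > 0:
        rng = np.random.default_rng(seed)
        gp = gp * np.exp(rng.normal(0.0, noise, gp.shape))
        gpp = gpp * np.exp(rng.normal(0.0, noise, gpp.shape))
    truth = {"g_prime_lve": g_prime_lve, "g_double_prime_lve": g_double_prime_lve,
             "tau_y": tau_y, "decay_slope": decay_slope}
    return OscSweep(stress, gp, gpp), truth


# --------------------------------------------------------------------------
# design tables

# composition grid (mg/mL) and pressures (kPa) mirroring the studied layout:
# alginate and hyaluronic acid each on a 4-level grid, five pressures per blend
DEFAULT_FACTOR_LEVELS = {
    "A": (10.0, 20.0, 40.0, 60.0),
    "B": (20.0, 40.0, 60.0, 80.0),
    "C": (55.0, 75.0, 95.0, 115.0, 135.0),
}


def _eval_term(term: str, cols: dict) -> np.ndarray:
    if term == "1":
        return np.ones_like(next(iter(cols.values())))
    out = None
    for part in term.split(":"):
        if "^" in part:
            fac, pw = part.split("^")
            val = cols[fac] ** int(pw)
        else:
            val = cols[part]
        out = val if out is None else out * val
    return out


def simulate_design(
    coefficients: dict,
    levels: dict | None = None,
    sigma: float | dict = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-factorial design table with polynomial-truth responses.

    ``coefficients`` maps each response name to a {term: coefficient} dict
    with terms over factors A (alginate mg/mL), B (hyaluronic acid mg/mL),
    C (pressure kPa), D (angle deg), e.g. ``{"SR": {"1": 3, "C": 0.05,
    "A:C": -1e-3, "A^2": 1e-4}}``.  Factors appearing in any term must have
    levels; defaults follow the studied 4 x 4 composition grid with five
    pressures and triplicate runs.  Gaussian noise of scale ``sigma``
    (scalar or per-response) is added independently per run.
    """
    if levels is None:
        used = {p.split("^")[0] for terms in coefficients.values()
                for t in terms for p in t.split(":") if t != "1"}
        levels = {f: DEFAULT_FACTOR_LEVELS[f] for f in sorted(used)
                  if f in DEFAULT_FACTOR_LEVELS}
        if "D" in used:
            levels["D"] = (60.0, 90.0, 120.0)
        if not levels:  # intercept-only truth still needs a factor layout
            levels = {"A": DEFAULT_FACTOR_LEVELS["A"],
                      "C": DEFAULT_FACTOR_LEVELS["C"]}
    factors = sorted(levels)
    grids = np.meshgrid(*[np.asarray(levels[f], dtype=float) for f in factors],
                        indexing="ij")
    flat = {f: g.ravel() for f, g in zip(factors, grids)}
    n_runs = next(iter(flat.values())).size

    rng = np.random.default_rng(seed)
    rows = {}
    for f in factors:
        rows[_FACTOR_COLUMNS[f]] = np.tile(flat[f], replicates)
    rows["replicate"] = np.repeat(np.arange(1, replicates + 1), n_runs)
    for resp, terms in coefficients.items():
        truth = np.zeros(n_runs)
        for term, coef in terms.items():
            truth = truth + coef * _eval_term(term, flat)
        s = sigma[resp] if isinstance(sigma, dict) else sigma
        y = np.tile(truth, replicates)
        if s > 0:
            y = y + rng.normal(0.0, s, y.size)
        rows[resp] = y
    return pd.DataFrame(rows)
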