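# inkwindow

Printability-window modeling for extrusion-bioprinting inks.

Formulating a hydrogel ink for extrusion bioprinting is usually a
trial-and-error exercise: for every candidate composition one must find the
pressures at which it extrudes, forms a uniform filament, and holds detailed
geometry. `inkwindow` packages the quantitative workflow that replaces that
loop for polysaccharide blend inks (e.g. alginate / hyaluronic acid):

1. **Rheology** — fit rotational shear-rate sweeps with the Cross model

   η(γ̇) = η∞ + (η₀ − η∞) / (1 + (k γ̇)^m)

   (η₀ zero-shear viscosity in Pa·s, k relaxation time in s, m = 1 − n with
   n the shear-thinning index), after truncating the high-rate tail corrupted
   by edge fracture; extract the linear-viscoelastic plateau moduli G′_LVE,
   G″_LVE and the yield-onset stress τ_y (intersection of log–log tangents
   before/after yielding) from oscillatory stress sweeps.
2. **Shape fidelity from images** — segment photographs of printed lines,
   angles and grids (local Otsu, hole filling, small-object removal) and
   compute:
   * UF′ = p / (2 (L + t_av)) — real filament perimeter over the perimeter of
     the equivalent rectangle; 1 ⇒ smooth extrusion,
   * SR = t_av / d_needle — spreading ratio,
   * AF = t_tip / t_line — width at an angle's vertex over arm width; > 1 ⇒
     material accumulation at sharp corners,
   * Pr = L² / (16 A) per grid pore — 1 for square pores, π/4 for circular,
   plus the gravimetric flow Qm = extruded mass / time (mg/s).
3. **Response surfaces** — empirical polynomial models of every rheological
   and printing yield over factors A (alginate mg/mL), B (hyaluronic acid
   mg/mL), C (pressure kPa) and, for AF, D (angle °), with backward
   elimination at p ≤ 0.1, Box–Cox residual normalization, and 95%
   prediction bands.
4. **Dynamic printability window** — the region of composition–pressure
   space where the models predict Qm > 0 and SR < 6, projectable onto the
   rheology surfaces ("what rheology must an ink have to print well here"),
   with the operating optimum located by Derringer–Suich desirability
   (Pr on target 1, SR minimized, overall D = geometric mean).

A seeded synthetic-fixture module generates all three input classes
(rheometer sweeps, rendered construct images, factorial design tables) with
exact ground truth, so the entire pipeline is testable without lab data.

## Worked example

```python
import inkwindow as iw
from inkwindow import synthetic as syn

# --- rheology: noisy Cross-law sweep with an edge-fracture artifact
curve, _ = syn.simulate_flow_curve(eta0=200.0, k=0.5, m=0.7,
                                   noise=0.01, seed=1, artifact=True)
trimmed = iw.truncate_edge_fracture(curve)     # drops the corrupted tail
fit = iw.fit_cross(trimmed, fix_eta_inf_zero=True)
# eta0 = 199.9 Pa.s, k = 0.497 s, m = 0.703, n = 0.297, r2 = 0.9999
# (kept 26/30 points)

# --- image metrics: a rendered 20 x 20 mm grid, 15% infill
img, _ = syn.render_construct(syn.RenderSpec(kind="grid", um_per_px=10))
mask = iw.segment_print(img, iw.SegmentationParams(fill_holes=True), "grid")
iw.compute_pr(mask).mean_pr                    # 0.993 (square pores -> ~1)

# --- surfaces, window, optimum
from inkwindow import response_surface as rs, window as win
design = syn.simulate_design(
    {"Qm": {"1": -2.0, "C": 0.04, "A": -0.02, "B": -0.01},
     "SR": {"1": 1.0, "C": 0.05, "A": -0.02, "B": -0.015},
     "Pr": {"1": 1.25, "C": -0.004, "A": 0.001, "B": 0.0005}},
    sigma={"Qm": 0.1, "SR": 0.2, "Pr": 0.02}, seed=1)
models = {name: rs.fit_rsm(design, name) for name in ("Qm", "SR", "Pr")}
grid = win.FactorGrid.from_ranges(
    {"A": (10, 60), "B": (20, 80), "C": (55, 135)}, resolution=21)
window = win.printability_window(models["Qm"], models["SR"], grid)
opt = win.optimize_desirability(models, win.DesirabilityConfig(), grid, window)
# printable cells: 5263/9261
# optimum {'A': 10.0, 'B': 66.0, 'C': 71.7}, D = 1.0
```

The optimum is the (alginate, HA, pressure) point inside the printable
window where the predicted Pr is closest to 1 while SR is smallest — the
composition and pressure to try first in the lab.

## Command line

The same workflow as a shell tool:

```sh
inkwindow simulate --seed 5 --out demo/            # synthetic inputs
inkwindow rheology --flow demo/flow_curve.csv --osc demo/osc_sweep.csv \
    --out demo/rheo.json
inkwindow measure --image demo/line.png line --image demo/grid.png grid \
    --out demo/metrics.json
inkwindow model --design demo/design.csv \
    --response Qm --response SR --response Pr --out demo/models.json
inkwindow window --models demo/models.json --out demo/win/
```

Every report carries a provenance block (config hash, seed, version);
identical inputs give byte-identical outputs.  The nozzle inner diameter and
the µm/px calibration are required configuration — there is no silent
default for physical scale.

## Acceptance script

`scripts/acceptance.py` recomputes the package's closed-form anchor
quantities — the printability index of an exactly square pore, the overall
desirability at a point with Pr on target and SR at its lower bound, and the
uniformity factor of a perfect rectangle — by calling the package's metric
and desirability functions at run time:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
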