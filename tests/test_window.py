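"""Printability window, rheology band projection and desirability optimum."""

import numpy as np
import pytest

from inkwindow import response_surface as rs
from inkwindow import synthetic as syn
from inkwindow import window as win


def planes_design(qm=("Qm", {"1": -60.0, "C": 1.0}),
                  sr=("SR", {"1": 0.0, "C": 0.05}),
                  levels=None):
    levels = levels or {"A": [10, 20, 40, 60],
                        "C": [40, 60, 80, 100, 120, 140]}
    coeffs = dict([qm, sr])
    return syn.simulate_design(coeffs, levels=levels, sigma=0.0, replicates=1)


def fit_all(design, names):
    return {n: rs.fit_rsm(design, n, transform="identity") for n in names}


class TestDesirabilityRamps:
    def test_min_boundaries_and_midpoint(self):
        assert win.desirability_min(2.0, 2.0, 5.0) == 1.0
        assert win.desirability_min(5.0, 2.0, 5.0) == 0.0
        assert win.desirability_min(3.5, 2.0, 5.0) == pytest.approx(0.5)

    def test_target_boundaries_and_midpoint(self):
        assert win.desirability_target(1.0, 0.5, 1.0, 1.5) == 1.0
        assert win.desirability_target(0.5, 0.5, 1.0, 1.5) == 0.0
        assert win.desirability_target(1.5, 0.5, 1.0, 1.5) == 0.0
        assert win.desirability_target(0.75, 0.5, 1.0, 1.5) == pytest.approx(0.5)

    def test_min_nonincreasing(self):
        y = np.linspace(0, 10, 301)
        d = win.desirability_min(y, 2.0, 5.0)
        assert np.all(np.diff(d) <= 0)

    def test_target_unimodal_peak_at_t(self):
        y = np.linspace(0, 2, 401)
        d = win.desirability_target(y, 0.5, 1.2, 1.8)
        assert d[np.argmin(np.abs(y - 1.2))] == pytest.approx(1.0, abs=5e-3)
        peak = np.argmax(d)
        assert np.all(np.diff(d[:peak]) >= -1e-12)
        assert np.all(np.diff(d[peak:]) <= 1e-12)

    def test_weights(self):
        assert win.desirability_min(3.5, 2.0, 5.0, w=2) == pytest.approx(0.25)

    def test_overall_geometric_mean(self):
        assert win.overall_desirability([1.0, 0.25]) == pytest.approx(0.5)
        assert win.overall_desirability([0.3, 0.0, 0.9]) == 0.0
        assert win.overall_desirability([1.0, 1.0]) == 1.0

    def test_overall_bounds_and_zero_rule(self):
        rng = np.random.default_rng(0)
        ds = rng.uniform(0, 1, size=(3, 50))
        D = win.overall_desirability(ds)
        assert np.all((D >= 0) & (D <= 1))
        k = ds.shape[0]
        assert np.all(D <= np.min(ds, axis=0) ** (1.0 / k) + 1e-12)
        assert win.overall_desirability([0.0, 0.7]) == 0.0


class TestWindow:
    def test_whole_grid_printable(self, quiet_warnings):
        d = planes_design(qm=("Qm", {"1": 1.0}), sr=("SR", {"1": 3.0}))
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 5),
                               "C": np.linspace(40, 140, 11)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        assert w.printable.all() and not w.empty

    def test_never_extruding_empty_flag(self, quiet_warnings):
        d = planes_design(qm=("Qm", {"1": -1.0}), sr=("SR", {"1": 3.0}))
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 5),
                               "C": np.linspace(40, 140, 11)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        assert w.empty and not w.printable.any()

    def test_analytic_planes_match_brute_force(self):
        d = planes_design()
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 6),
                               "C": np.linspace(40, 140, 21)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        pts = grid.points()
        # independent per-cell constraint evaluation: bit-identical
        brute = np.array([
            models["Qm"].predict(pts.iloc[[i]])[0] > 0.0
            and models["SR"].predict(pts.iloc[[i]])[0] < 6.0
            for i in range(len(pts))])
        assert np.array_equal(w.printable, brute)
        # analytic region 60 < C < 120, away from the float-sensitive
        # boundary cells themselves
        c = pts["pressure_kPa"].to_numpy()
        interior = (np.abs(c - 60.0) > 1e-6) & (np.abs(c - 120.0) > 1e-6)
        analytic = (c > 60.0) & (c < 120.0)
        assert np.array_equal(w.printable[interior], analytic[interior])

    def test_threshold_monotone_containment(self):
        d = planes_design()
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 6),
                               "C": np.linspace(40, 140, 21)})
        prev = None
        for thr in (6.0, 5.0, 4.0, 3.0):
            w = win.printability_window(models["Qm"], models["SR"], grid,
                                        sr_threshold=thr)
            if prev is not None:
                assert np.all(prev | ~w.printable)  # containment
            prev = w.printable


class TestRheologyBands:
    def test_monotone_plane_band(self, quiet_warnings):
        d = planes_design(qm=("Qm", {"1": 1.0}), sr=("SR", {"1": 3.0}))
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 6),
                               "B": np.linspace(20, 80, 4),
                               "C": np.linspace(40, 140, 5)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        de = syn.simulate_design({"eta0": {"1": 10.0, "A": 1.0}},
                                 levels={"A": [10, 20, 40, 60],
                                         "B": [20, 40, 60, 80]},
                                 sigma=0.0, replicates=1)
        eta = rs.fit_rsm(de, "eta0", transform="identity")
        bands = win.map_window_to_rheology(w, {"eta0": eta})
        assert bands["eta0"] == (pytest.approx(20.0), pytest.approx(70.0))

    def test_quadratic_band_equals_exhaustive(self, quiet_warnings):
        d = planes_design()
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 6),
                               "B": np.linspace(20, 80, 4),
                               "C": np.linspace(40, 140, 11)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        de = syn.simulate_design(
            {"k": {"1": 0.1, "A": 0.01, "A^2": 2e-4, "B": -0.002}},
            levels={"A": [10, 20, 40, 60], "B": [20, 40, 60, 80]},
            sigma=0.0, replicates=1)
        km = rs.fit_rsm(de, "k", transform="identity")
        bands = win.map_window_to_rheology(w, {"k": km})
        vals = km.predict(w.printable_points())
        assert bands["k"] == (pytest.approx(vals.min()),
                              pytest.approx(vals.max()))

    def test_empty_window_no_bands(self, quiet_warnings):
        d = planes_design(qm=("Qm", {"1": -1.0}), sr=("SR", {"1": 3.0}))
        models = fit_all(d, ("Qm", "SR"))
        grid = win.FactorGrid({"A": np.linspace(10, 60, 5),
                               "C": np.linspace(40, 140, 5)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        assert win.map_window_to_rheology(w, {}) == {}


class TestOptimizer:
    def setup_models(self, a=0.01, c0=80.0, s1=0.03, seed=0):
        d = syn.simulate_design(
            {"Pr": {"1": 1 - a * c0, "C": a},
             "SR": {"1": 1.0, "C": s1},
             "Qm": {"1": -50.0, "C": 1.0}},
            levels={"A": [20, 40], "B": [40, 60],
                    "C": [55, 75, 95, 115, 135]},
            sigma=0.0, replicates=1)
        return fit_all(d, ("Pr", "SR", "Qm"))

    @staticmethod
    def dense_oracle(a, c0, s1, grid_c):
        """Independent 1-D dense-scan maximization of D over pressure.

        Bounds L/U come from the printable grid cells (matching their stated
        definition); the scan itself is dense and masks cells violating the
        Qm > 0 / SR < 6 printability constraints.
        """

        def pr(C):
            return 1 + a * (C - c0)

        def sr(C):
            return 1 + s1 * C

        printable_cells = grid_c[(grid_c > 50.0) & (sr(grid_c) < 6.0)]
        Lp, Up = pr(printable_cells).min(), pr(printable_cells).max()
        Ls, Us = sr(printable_cells).min(), sr(printable_cells).max()
        C = np.linspace(55, 135, 400001)
        dp = np.where(C <= c0, (pr(C) - Lp) / (1 - Lp),
                      (Up - pr(C)) / (Up - 1))
        ds = (Us - sr(C)) / (Us - Ls)
        D = np.sqrt(np.clip(dp, 0, 1) * np.clip(ds, 0, 1))
        D[(C <= 50.0) | (sr(C) >= 6.0)] = 0.0
        return C[np.argmax(D)], D.max()

    def test_monotone_sr_pr_on_target(self, quiet_warnings):
        # Pr identically 1 and SR increasing in C: optimum at the lowest
        # printable pressure
        d = syn.simulate_design(
            {"Pr": {"1": 1.0}, "SR": {"1": 1.0, "C": 0.03},
             "Qm": {"1": -50.0, "C": 1.0}},
            levels={"A": [20, 40], "C": [55, 75, 95, 115, 135]},
            sigma=0.0, replicates=1)
        models = fit_all(d, ("Pr", "SR", "Qm"))
        grid = win.FactorGrid({"A": np.linspace(20, 40, 3),
                               "C": np.linspace(55, 135, 17)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        opt = win.optimize_desirability(models, win.DesirabilityConfig(),
                                        grid, w)
        assert opt.grid_point["C"] == pytest.approx(55.0)

    def test_quadratic_pr_linear_sr_vs_oracle(self, quiet_warnings):
        for a, c0, s1 in [(0.01, 80.0, 0.03), (0.02, 100.0, 0.02),
                          (0.005, 70.0, 0.041)]:
            models = self.setup_models(a, c0, s1)
            grid = win.FactorGrid({"A": np.linspace(20, 40, 3),
                                   "B": np.linspace(40, 60, 3),
                                   "C": np.linspace(55, 135, 17)})
            w = win.printability_window(models["Qm"], models["SR"], grid)
            opt = win.optimize_desirability(models, win.DesirabilityConfig(),
                                            grid, w)
            c_star, d_star = self.dense_oracle(a, c0, s1, grid.axes["C"])
            step = 80.0 / 16.0
            assert abs(opt.grid_point["C"] - c_star) <= step + 1e-9
            assert opt.point["C"] == pytest.approx(c_star, abs=1e-3)
            assert opt.desirability == pytest.approx(d_star, abs=1e-6)

    def test_tie_break_prefers_low_pressure_and_polymer(self, quiet_warnings):
        d = syn.simulate_design(
            {"Pr": {"1": 1.0}, "SR": {"1": 3.0}, "Qm": {"1": 1.0}},
            levels={"A": [20, 40], "C": [55, 75, 95]},
            sigma=0.0, replicates=1)
        models = fit_all(d, ("Pr", "SR", "Qm"))
        grid = win.FactorGrid({"A": np.linspace(20, 40, 3),
                               "C": np.linspace(55, 95, 5)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        opt = win.optimize_desirability(models, win.DesirabilityConfig(),
                                        grid, w)
        assert opt.grid_point["C"] == pytest.approx(55.0)
        assert opt.grid_point["A"] == pytest.approx(20.0)

    def test_impossible_target_flagged(self, quiet_warnings):
        models = self.setup_models()
        grid = win.FactorGrid({"A": np.linspace(20, 40, 3),
                               "B": np.linspace(40, 60, 3),
                               "C": np.linspace(55, 135, 9)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        config = win.DesirabilityConfig(yields={
            "Pr": win.YieldSpec(mode="target", L=10.0, T=11.0, U=12.0),
            "SR": win.YieldSpec(mode="minimize"),
        })
        opt = win.optimize_desirability(models, config, grid, w)
        assert opt.no_desirable_region

    def test_empty_window_no_optimum(self, quiet_warnings):
        d = planes_design(qm=("Qm", {"1": -1.0}), sr=("SR", {"1": 3.0}))
        models = fit_all(d, ("Qm", "SR"))
        models["Pr"] = models["SR"]
        grid = win.FactorGrid({"A": np.linspace(10, 60, 5),
                               "C": np.linspace(40, 140, 5)})
        w = win.printability_window(models["Qm"], models["SR"], grid)
        opt = win.optimize_desirability(models, win.DesirabilityConfig(),
                                        grid, w)
        assert opt.no_desirable_region


class TestFactorGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            win.FactorGrid({"A": [1.0]})
        with pytest.raises(ValueError):
            win.FactorGrid({"A": [2.0, 1.0]})

    def test_points_row_major(self):
        g = win.FactorGrid({"A": [1.0, 2.0], "C": [10.0, 20.0, 30.0]})
        pts = g.points()
        assert list(pts["alginate_mg_ml"][:3]) == [1.0, 1.0, 1.0]
        assert list(pts["pressure_kPa"][:3]) == [10.0, 20.0, 30.0]
        assert len(pts) == 6

    def test_yieldspec_validation(self):
        with pytest.raises(ValueError):
            win.YieldSpec(mode="target")  # T missing
        with pytest.raises(ValueError):
            win.YieldSpec(mode="minimize", L=5.0, U=2.0)
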