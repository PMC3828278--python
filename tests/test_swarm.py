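"""Particle-swarm optimisation and sensitivity bounds."""

import numpy as np
import pytest

import glosens as g
from glosens.swarm import SwarmSettings, bounds_vs_sampling, pso_minimize, sensitivity_bounds

FLUX = g.OutputSpec("flux", "step1")
CONC = g.OutputSpec("concentration", "S1")


def _unit_domain(**named):
    ref = g.ParameterSet({k: 0.5 * (lo + hi) for k, (lo, hi) in named.items()})
    return g.ParameterDomain(ref, 0.0, overrides=dict(named))


class TestPsoMinimize:
    def test_quadratic_beats_grid_oracle(self):
        dom = _unit_domain(x=(0.0, 1.0))
        settings = SwarmSettings(swarm_size=10, iteration_limit=19, seed=3)  # 200 evals
        res = pso_minimize(lambda ps: (ps["x"] - 0.3) ** 2, dom, settings)
        grid_best = min((x / 1000 - 0.3) ** 2 for x in range(1001))
        assert res.n_evals == 200
        assert res.value < 1e-4
        assert res.value <= grid_best + 1e-4

    def test_degenerate_domain_single_evaluation(self, chain):
        model, _ = chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.0)
        res = pso_minimize(lambda ps: ps["k1"], dom, SwarmSettings(seed=0))
        assert res.n_evals == 1
        assert res.value == pytest.approx(2.0)

    def test_rastrigin_benchmark(self):
        def rastrigin(ps):
            x, y = ps["x"], ps["y"]
            return (
                20.0
                + x * x - 10.0 * np.cos(2 * np.pi * x)
                + y * y - 10.0 * np.cos(2 * np.pi * y)
            )

        wins = 0
        for seed in range(10):
            dom = _unit_domain(x=(-5.12, 5.12), y=(-5.12, 5.12))
            dom.reference["x"] = 4.0  # start the pinned particle off-optimum
            dom.reference["y"] = 4.0
            res = pso_minimize(
                rastrigin, dom, SwarmSettings(swarm_size=20, iteration_limit=500, seed=seed)
            )
            wins += res.value < 1.0
        assert wins >= 9

    def test_deterministic_given_seed(self):
        dom = _unit_domain(x=(0.0, 1.0), y=(0.0, 1.0))
        obj = lambda ps: (ps["x"] - 0.2) ** 2 + (ps["y"] - 0.8) ** 2
        s = SwarmSettings(swarm_size=8, iteration_limit=20, seed=11)
        a = pso_minimize(obj, dom, s)
        b = pso_minimize(obj, dom, s)
        assert a.value == b.value and a.params == b.params

    def test_positions_stay_in_domain(self):
        seen = []
        dom = _unit_domain(x=(2.0, 3.0))
        pso_minimize(lambda ps: seen.append(ps["x"]) or ps["x"], dom,
                     SwarmSettings(swarm_size=5, iteration_limit=30, seed=2))
        assert all(2.0 <= x <= 3.0 for x in seen)

    def test_all_undefined_fails_cleanly(self):
        dom = _unit_domain(x=(0.0, 1.0))
        res = pso_minimize(lambda ps: None, dom, SwarmSettings(swarm_size=4, iteration_limit=3, seed=0))
        assert not res.ok
        assert res.n_undefined == res.n_evals

    def test_settings_validation(self):
        with pytest.raises(Exception):
            SwarmSettings(swarm_size=1)
        with pytest.raises(Exception):
            SwarmSettings(iteration_limit=0)


class TestSensitivityBounds:
    def test_structurally_constant_coefficient(self, chain):
        model, _ = chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.5)
        b = sensitivity_bounds(model, dom, FLUX, "k1",
                               SwarmSettings(swarm_size=8, iteration_limit=10, seed=1))
        assert b.lower == pytest.approx(1.0, abs=1e-9)
        assert b.upper == pytest.approx(1.0, abs=1e-9)

    def test_constant_negative_coefficient(self, chain):
        # S* = k1 X0 / k2: scaled coefficient to k2 constant at -1
        # (forward differencing sees -1/(1+h) everywhere)
        model, _ = chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.5)
        b = sensitivity_bounds(model, dom, CONC, "k2",
                               SwarmSettings(swarm_size=8, iteration_limit=10, seed=1))
        assert b.lower == pytest.approx(-1.0, abs=2e-3)
        assert b.upper == pytest.approx(-1.0, abs=2e-3)
        assert b.upper - b.lower < 1e-9

    def test_bounds_match_grid_oracle(self, reversible_chain):
        """PSO bounds vs an exhaustive 200x200 grid of the symbolic
        coefficient on the 2-parameter reversible chain."""
        model, oracle = reversible_chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.5)
        b = sensitivity_bounds(
            model, dom, FLUX, "k1",
            SwarmSettings(swarm_size=15, iteration_limit=40, seed=7),
            rel_step=1e-4,
        )
        (lo1, hi1), (lo2, hi2) = zip(*dom.bounds())
        grid = [
            oracle.flux_control_at({"k1": a, "k2": c})["step1"]
            for a in np.linspace(lo1, hi1, 200)
            for c in np.linspace(lo2, hi2, 200)
        ]
        gmin, gmax = min(grid), max(grid)
        assert b.lower == pytest.approx(gmin, rel=0.01, abs=1e-4)
        assert b.upper == pytest.approx(gmax, rel=0.01, abs=1e-4)

    def test_zero_band_bounds_equal_local(self, reversible_chain):
        model, _ = reversible_chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.0)
        local = g.scaled_sensitivity(model, model.reference_parameters(), FLUX, "k1").value
        b = sensitivity_bounds(model, dom, FLUX, "k1", SwarmSettings(seed=1))
        assert b.lower == pytest.approx(local, abs=1e-12)
        assert b.upper == pytest.approx(local, abs=1e-12)
        assert b.n_evals == 2  # one evaluation per optimisation direction

    def test_bounds_widen_with_band(self, reversible_chain):
        model, _ = reversible_chain
        widths = []
        for band in (0.1, 0.3, 0.5):
            dom = g.ParameterDomain(model.reference_parameters(), band)
            b = sensitivity_bounds(model, dom, FLUX, "k1",
                                   SwarmSettings(swarm_size=10, iteration_limit=25, seed=5))
            widths.append((b.lower, b.upper))
        for (lo1, hi1), (lo2, hi2) in zip(widths, widths[1:]):
            assert lo2 <= lo1 + 1e-9 and hi2 >= hi1 - 1e-9

    def test_argpoints_inside_domain_and_replayable(self, reversible_chain):
        model, _ = reversible_chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.4)
        b = sensitivity_bounds(model, dom, FLUX, "k1",
                               SwarmSettings(swarm_size=10, iteration_limit=20, seed=3))
        assert dom.contains(b.argmin) and dom.contains(b.argmax)
        replay = g.scaled_sensitivity(model, b.argmax, FLUX, "k1").value
        assert replay == pytest.approx(b.upper, abs=1e-9)

    def test_execution_order_independent(self, reversible_chain):
        model, _ = reversible_chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.3)
        s = SwarmSettings(swarm_size=8, iteration_limit=10, seed=42)
        first = sensitivity_bounds(model, dom, FLUX, "k1", s)
        # interleave an unrelated job, then repeat: identical results
        sensitivity_bounds(model, dom, FLUX, "k2", s)
        second = sensitivity_bounds(model, dom, FLUX, "k1", s)
        assert (first.lower, first.upper) == (second.lower, second.upper)


class TestBoundsVsSampling:
    def test_comparison_is_reported(self, reversible_chain):
        model, _ = reversible_chain
        dom = g.ParameterDomain(model.reference_parameters(), 0.5)
        b = sensitivity_bounds(model, dom, FLUX, "k1",
                               SwarmSettings(swarm_size=10, iteration_limit=20, seed=9))
        records = g.run_sampling_gsa(model, dom, FLUX, 100, seed=9, parameters=["k1"])
        report = bounds_vs_sampling(b, records["k1"])
        assert report["comparable"]
        assert report["sampling_min"] >= report["lower_bound"] - 1e-6 or report["lower_shortfall"] > 0
        assert {"bounds_dominate", "upper_shortfall"} <= set(report)
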