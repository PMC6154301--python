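"""IMEX stepping: fixed points, determinism, noise statistics, stability."""

import math

import numpy as np
import pytest

from cellpass import (
    CellParams,
    ChemokineSource,
    SignalField,
    StepConfig,
    World,
    init_cell_2d,
    run_scenario,
    wiener_increment,
)
from cellpass.exceptions import IntegrationUnstableError
from cellpass.integrator import advance, step_membrane, step_nucleus
from cellpass.scenarios import Scenario, build_scenario


def free_cell(params=None, center=(0.0, 0.0)):
    return init_cell_2d(params or CellParams(), center=center)


def empty_world():
    return World([])


class TestWiener:
    def test_sample_variance_matches_dt(self, rng):
        dt = 1e-4
        w = wiener_increment(2, dt, rng, n=50_000).ravel()
        n = len(w)
        se = dt * math.sqrt(2.0 / (n - 1))
        assert abs(w.var(ddof=1) - dt) < 3 * se
        assert abs(w.mean()) < 3 * math.sqrt(dt / n)

    def test_seeded_reproducibility(self):
        a = wiener_increment(3, 0.01, np.random.default_rng(5), n=10)
        b = wiener_increment(3, 0.01, np.random.default_rng(5), n=10)
        assert np.array_equal(a, b)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            wiener_increment(2, 0.0, np.random.default_rng(0))


class TestMembraneStep:
    def test_equilibrium_is_fixed_point(self):
        st = free_cell()
        cfg = StepConfig(dt=1e-4, eta=0.0)
        x_new, contact = step_membrane(st, None, empty_world(), cfg,
                                       np.random.default_rng(0))
        assert np.allclose(x_new, st.x, atol=1e-14)
        assert not contact.any()

    def test_scalar_relaxation_closed_form(self):
        # 1D analogue: x=0 relaxing to target 1 gives dt*a/(1+dt*a)
        p = CellParams(alpha=250.0, beta=0.0, eta=0.0)
        st = free_cell(p)
        st.x = st.x.copy()
        st.x[0] = st.x_n[0] + st.xhat[0] + np.array([-1.0, 0.0])  # displaced by 1
        cfg = StepConfig(dt=1e-4, eta=0.0)
        x_new, _ = step_membrane(st, None, empty_world(), cfg,
                                 np.random.default_rng(0))
        moved = (x_new[0] - st.x[0])[0]
        assert moved == pytest.approx(1e-4 * 250 / (1 + 1e-4 * 250), rel=1e-12)
        assert moved == pytest.approx(0.02439, abs=1e-5)

    def test_pure_chemotaxis_follows_imex_drift(self):
        p = CellParams(alpha=0.0, alpha_n=0.0, beta=60.0, eta=0.0)
        st = free_cell(p, center=(0.0, 0.0))
        field = SignalField([ChemokineSource(np.array([100.0, 0.0]), 1.2e6)])
        cfg = StepConfig(dt=1e-4, eta=0.0)
        x_new, _ = step_membrane(st, field, empty_world(), cfg,
                                 np.random.default_rng(0))
        s, S = field.imex_coefficients(st.x)
        expected = (st.x + cfg.dt * p.beta * S) / (1 + cfg.dt * p.beta * s[:, None])
        assert np.allclose(x_new, expected, atol=1e-14)


class TestNucleusStep:
    def test_equilibrium_fixed_point(self):
        st = free_cell()
        cfg = StepConfig(dt=1e-4, eta=0.0)
        xn_new, _ = step_nucleus(st, st.x, empty_world(), cfg,
                                 np.random.default_rng(0))
        assert np.allclose(xn_new, st.x_n, atol=1e-14)

    def test_nucleus_follows_outwardly_displaced_membrane(self):
        st = free_cell()
        cfg = StepConfig(dt=1e-4, eta=0.0)
        x_shift = st.x + np.array([0.5, 0.0])  # membrane pushed +x
        xn_new, _ = step_nucleus(st, x_shift, empty_world(), cfg,
                                 np.random.default_rng(0))
        assert np.all(xn_new[:, 0] > st.x_n[:, 0])

    def test_stiff_nucleus_limit_pins_to_anchor(self):
        p = CellParams(alpha_n=1e9)
        st = free_cell(p)
        st.x_n = st.x_n + 0.3
        cfg = StepConfig(dt=1e-4, eta=0.0)
        xn_new, _ = step_nucleus(st, st.x, empty_world(), cfg,
                                 np.random.default_rng(0))
        anchor = st.x_c + st.xhat_n
        assert np.allclose(xn_new, anchor, atol=1e-4)


class TestAdvance:
    def scenario_free(self, params=None, source=None):
        cell = free_cell(params)
        srcs = [ChemokineSource(np.array(source), 1.2e6)] if source else []
        return Scenario("free", [cell], SignalField(srcs), empty_world())

    def test_equilibrium_persists_1000_steps(self):
        sc = self.scenario_free()
        cfg = StepConfig(dt=1e-4, eta=0.0, t_end=0.1, record_every=None)
        traj = run_scenario(sc, cfg)
        assert np.abs(traj.membrane[-1] - sc.cells[0].x).max() < 1e-10

    def test_monotone_approach_to_distant_source(self):
        sc = self.scenario_free(source=(500.0, 0.0))
        cell = sc.cells[0].copy()
        rng = np.random.default_rng(0)
        cfg = StepConfig(dt=1e-4, eta=0.0)
        xs = []
        for k in range(100):
            advance(cell, sc.field, sc.world, cfg, rng, k * 1e-4)
            xs.append(cell.membrane_centroid()[0])
        assert np.all(np.diff(xs) > 0)

    def test_shape_memory_relaxation_monotone(self):
        # displaced membrane relaxes monotonically back (beta=eta=0)
        p = CellParams(beta=0.0)
        sc = self.scenario_free(p)
        cell = sc.cells[0].copy()
        cell.x = cell.x * 1.2  # inflate
        cfg = StepConfig(dt=1e-4, eta=0.0)
        rng = np.random.default_rng(0)
        errs = []
        for k in range(200):
            advance(cell, None, sc.world, cfg, rng, 0.0)
            errs.append(np.linalg.norm(cell.x - (cell.x_n + cell.xhat)))
        assert np.all(np.diff(errs) < 0)
        assert errs[-1] < errs[0] / 50

    def test_deterministic_runs_bit_identical(self):
        cfgs = StepConfig(dt=1e-4, eta=0.0, t_end=0.02, record_every=10)
        t1 = run_scenario(build_scenario("channel"), cfgs)
        t2 = run_scenario(build_scenario("channel"), cfgs)
        assert np.array_equal(t1.membrane, t2.membrane)
        assert np.array_equal(t1.nucleus, t2.nucleus)

    def test_seeded_noise_reproducible(self):
        cfgs = StepConfig(dt=1e-4, eta=5.0, seed=77, t_end=0.02, record_every=10)
        t1 = run_scenario(build_scenario("channel"), cfgs)
        t2 = run_scenario(build_scenario("channel"), cfgs)
        assert np.array_equal(t1.membrane, t2.membrane)
        t3 = run_scenario(build_scenario("channel"),
                          StepConfig(dt=1e-4, eta=5.0, seed=78, t_end=0.02,
                                     record_every=10))
        assert not np.array_equal(t1.membrane, t3.membrane)

    def test_instability_aborts_with_diagnostic(self):
        # a noise kick far beyond the cell radius must abort, not propagate
        sc = self.scenario_free()
        cfg = StepConfig(dt=0.01, eta=1e4, seed=0, t_end=1.0, record_every=None)
        with pytest.raises(IntegrationUnstableError, match="dt"):
            run_scenario(sc, cfg)

    def test_implicit_relaxation_stable_at_large_dt(self):
        # relaxation alone cannot blow up for any dt (implicit coefficients)
        p = CellParams(beta=0.0)
        sc = self.scenario_free(p)
        cell = sc.cells[0].copy()
        cell.x = cell.x * 1.5
        cfg = StepConfig(dt=1.0, eta=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            advance(cell, None, sc.world, cfg, rng, 0.0)
        assert np.linalg.norm(cell.x - (cell.x_n + cell.xhat)) < 1e-6

    def test_source_consumption_and_relaxation_tail(self):
        cell = free_cell(center=(0.0, 0.0))
        field = SignalField([ChemokineSource(np.array([30.0, 0.0]), 5e6)])
        sc = Scenario("free", [cell], field, empty_world())
        cfg = StepConfig(dt=1e-4, eta=0.0, t_end=2.0, record_every=500)
        traj = run_scenario(sc, cfg)
        assert "source_consumed" in traj.events
        t_c = traj.events["source_consumed"]
        # run stopped a relaxation tail after consumption, not at t_end
        assert traj.times[-1] == pytest.approx(t_c + 0.05, abs=1e-3)
        # shape recovered: membrane RMS distance to equilibrium below 0.1 um
        final_m, final_n = traj.membrane[-1], traj.nucleus[-1]
        rms = np.sqrt(np.mean(np.sum((final_m - (final_n + sc.cells[0].xhat)) ** 2,
                                     axis=1)))
        assert rms < 0.1
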