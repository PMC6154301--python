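"""Chemoattractant field: fundamental solutions, IMEX gradient, consumption."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellpass import ChemokineSource, SignalField, consume_sources
from cellpass.exceptions import GeometryError, SingularEvaluationError


def make_field(positions, rates, D=3600.0, dim=2, form="paper"):
    srcs = [ChemokineSource(np.array(p, dtype=float), r) for p, r in zip(positions, rates)]
    return SignalField(srcs, D=D, dim=dim, form=form)


class TestConcentration2D:
    def test_unit_distance_gives_zero(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        assert f.concentration([1.0, 0.0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_log_solution_at_10um(self):
        # direct arithmetic: -gamma/(2 pi D) * ln 10
        f = make_field([(0.0, 0.0)], [1.2e6])
        expected = -1.2e6 / (2 * math.pi * 3600.0) * math.log(10.0)
        assert f.concentration([10.0, 0.0]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-122.2, abs=0.1)

    def test_negative_far_field_permitted(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        assert f.concentration([50.0, 0.0]) < 0.0

    def test_coincident_sources_double(self):
        one = make_field([(0.0, 0.0)], [1.2e6])
        two = make_field([(0.0, 0.0), (0.0, 0.0)], [1.2e6, 1.2e6])
        x = [3.0, 4.0]
        assert two.concentration(x) == pytest.approx(2 * one.concentration(x))

    def test_inactive_source_contributes_nothing(self):
        f = make_field([(0.0, 0.0), (5.0, 5.0)], [1.2e6, 9e5])
        f.sources[1].active = False
        ref = make_field([(0.0, 0.0)], [1.2e6])
        x = [7.0, -2.0]
        assert f.concentration(x) == pytest.approx(ref.concentration(x))
        assert np.allclose(f.imex_gradient(np.array(x), np.array(x)),
                           ref.imex_gradient(np.array(x), np.array(x)))

    def test_singular_evaluation_raises(self):
        f = make_field([(1.0, 2.0)], [1.2e6])
        with pytest.raises(SingularEvaluationError):
            f.concentration([1.0, 2.0])
        with pytest.raises(SingularEvaluationError):
            f.imex_gradient(np.array([0.0, 0.0]), np.array([1.0, 2.0]))


class TestImexGradient:
    def test_zero_at_source(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        g = f.imex_gradient(np.array([0.0, 0.0]), np.array([10.0, 0.0]))
        assert np.allclose(g, 0.0)

    def test_magnitude_and_direction_at_10um(self):
        # gamma/(pi D r) toward the source for x_new = x_old
        f = make_field([(0.0, 0.0)], [1.2e6])
        x = np.array([10.0, 0.0])
        g = f.imex_gradient(x, x)
        assert np.linalg.norm(g) == pytest.approx(1.2e6 / (math.pi * 3600.0 * 10.0),
                                                  rel=1e-12)
        assert np.linalg.norm(g) == pytest.approx(10.61, abs=0.01)
        assert g[0] < 0 and g[1] == pytest.approx(0.0)

    def test_doubling_diffusivity_halves_gradient(self):
        x = np.array([7.0, 3.0])
        g1 = make_field([(0.0, 0.0)], [1.2e6], D=3600.0).imex_gradient(x, x)
        g2 = make_field([(0.0, 0.0)], [1.2e6], D=7200.0).imex_gradient(x, x)
        assert np.allclose(g1, 2.0 * g2)

    def test_imex_split_uses_old_denominator(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        x_new = np.array([5.0, 0.0])
        x_old = np.array([10.0, 0.0])
        g = f.imex_gradient(x_new, x_old)
        expected = 1.2e6 * (-5.0) / (math.pi * 3600.0 * 100.0)
        assert g[0] == pytest.approx(expected, rel=1e-12)

    def test_drift_is_twice_the_analytic_log_gradient(self):
        # regression pin: the pi*D convention is a factor 2 above the
        # analytic gradient of the logarithmic solution
        f = make_field([(0.0, 0.0)], [1.2e6])
        x = np.array([8.0, 0.0])
        analytic = 1.2e6 / (2 * math.pi * 3600.0 * 8.0)
        assert np.linalg.norm(f.imex_gradient(x, x)) == pytest.approx(2 * analytic,
                                                                      rel=1e-12)

    @given(st.floats(2.0, 80.0), st.floats(0.0, 2 * math.pi))
    def test_gradient_points_toward_source(self, r, th):
        f = make_field([(1.0, -2.0)], [1.2e6])
        x = np.array([1.0 + r * math.cos(th), -2.0 + r * math.sin(th)])
        g = f.imex_gradient(x, x)
        to_src = np.array([1.0, -2.0]) - x
        cos = g @ to_src / (np.linalg.norm(g) * np.linalg.norm(to_src))
        assert cos == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(1, 5))
    def test_superposition(self, k):
        rng = np.random.default_rng(k)
        pos = rng.uniform(-20, 20, (k, 2))
        rates = rng.uniform(1e5, 2e6, k)
        x = np.array([40.0, 31.0])
        total = make_field(pos, rates).imex_gradient(x, x)
        parts = sum(make_field([p], [r]).imex_gradient(x, x)
                    for p, r in zip(pos, rates))
        assert np.allclose(total, parts, rtol=1e-12)
        ctot = make_field(pos, rates).concentration(x)
        cparts = sum(make_field([p], [r]).concentration(x) for p, r in zip(pos, rates))
        assert ctot == pytest.approx(cparts, rel=1e-12)


class TestGreens3D:
    def test_paper_form_inverse_square(self):
        f = make_field([(0.0, 0.0, 0.0)], [1.2e6], dim=3, form="paper")
        r = 10.0
        expected = 1.2e6 / (4 * math.pi * 3600.0 * r**2)
        assert f.concentration([r, 0.0, 0.0]) == pytest.approx(expected, rel=1e-12)

    def test_paper_form_gradient(self):
        f = make_field([(0.0, 0.0, 0.0)], [1.2e6], dim=3, form="paper")
        x = np.array([10.0, 0.0, 0.0])
        g = f.imex_gradient(x, x)
        expected = 1.2e6 * 2 * 10.0 / (4 * math.pi * 3600.0 * 10.0**4)
        assert np.linalg.norm(g) == pytest.approx(expected, rel=1e-12)

    def test_physical_form_standard_fundamental_solution(self):
        f = make_field([(0.0, 0.0, 0.0)], [1.2e6], dim=3, form="physical")
        r = 10.0
        assert f.concentration([r, 0.0, 0.0]) == pytest.approx(
            1.2e6 / (4 * math.pi * 3600.0 * r), rel=1e-12)
        x = np.array([r, 0.0, 0.0])
        g = f.imex_gradient(x, x)
        assert np.linalg.norm(g) == pytest.approx(
            1.2e6 / (4 * math.pi * 3600.0 * r**2), rel=1e-12)


class TestConsumption:
    def square(self, side=10.0):
        s = side / 2
        return np.array([[-s, -s], [s, -s], [s, s], [-s, s]])

    def test_source_at_centroid_becomes_inactive(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        consume_sources(f, self.square())
        assert not f.sources[0].active

    def test_far_source_unchanged(self):
        f = make_field([(100.0, 0.0)], [1.2e6])
        consume_sources(f, self.square())
        assert f.sources[0].active

    def test_boundary_point_counts_as_inside(self):
        f = make_field([(5.0, 0.0)], [1.2e6])
        consume_sources(f, self.square())
        assert not f.sources[0].active

    def test_deactivation_is_permanent(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        consume_sources(f, self.square())
        consume_sources(f, self.square(side=0.1) + 50.0)
        assert not f.sources[0].active

    def test_open_polygon_rejected(self):
        f = make_field([(0.0, 0.0)], [1.2e6])
        with pytest.raises(GeometryError):
            consume_sources(f, np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_3d_mesh_containment(self):
        from cellpass import CellParams, init_cell_3d

        st3 = init_cell_3d(CellParams(R=10.0, R_n=8.0, N=12, M=12))
        f = make_field([(0.0, 0.0, 0.0), (30.0, 0.0, 0.0)], [1e6, 1e6], dim=3)
        consume_sources(f, st3.x, faces=st3.faces)
        assert not f.sources[0].active
        assert f.sources[1].active
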