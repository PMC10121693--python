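"""Migration observables: N_f, H, percent changes, argmax refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decoychemo import (
    build_grid,
    find_unimodal_argmax,
    fl1h_rescale,
    migrated_count,
    penetration_depth,
    percent_change,
)
from decoychemo.observables import MigrationSummary


@pytest.fixture(scope="module")
def fgrid(dimless_module):
    return build_grid(dimless_module, h=0.02)


@pytest.fixture(scope="module")
def dimless_module():
    from decoychemo import DimensionalParameters, nondimensionalize

    return nondimensionalize(DimensionalParameters())


class TestMigratedCount:
    def test_unit_profile(self, fgrid):
        n = np.ones(fgrid.n_filter_nodes)
        assert migrated_count(n, 4e5, fgrid) == pytest.approx(4e5)

    def test_zero_profile(self, fgrid):
        assert migrated_count(np.zeros(fgrid.n_filter_nodes), 4e5, fgrid) == 0.0

    def test_linear_profile_exact(self, fgrid):
        x = np.linspace(0, 1, fgrid.n_filter_nodes)
        assert migrated_count(x, 2.0, fgrid) == pytest.approx(1.0)

    def test_additive_over_node_aligned_split(self, fgrid):
        rng = np.random.default_rng(3)
        n = rng.uniform(0, 1, fgrid.n_filter_nodes)
        mid = fgrid.n_filter_nodes // 2
        whole = np.trapezoid(n, dx=fgrid.h)
        parts = (np.trapezoid(n[:mid + 1], dx=fgrid.h)
                 + np.trapezoid(n[mid:], dx=fgrid.h))
        assert parts == pytest.approx(whole, rel=1e-14)

    def test_negative_density_rejected(self, fgrid):
        n = np.zeros(fgrid.n_filter_nodes)
        n[3] = -1.0
        with pytest.raises(ValueError):
            migrated_count(n, 1.0, fgrid)


class TestPenetrationDepth:
    def test_everywhere_above_threshold(self, fgrid):
        n = np.full(fgrid.n_filter_nodes, 1.0)
        assert penetration_depth(n, 2.0, fgrid) == 1.0

    def test_everywhere_below_threshold(self, fgrid):
        n = np.full(fgrid.n_filter_nodes, 0.1)
        assert penetration_depth(n, 2.0, fgrid) == 0.0

    def test_step_profile_front(self, fgrid):
        x = np.linspace(0, 1, fgrid.n_filter_nodes)
        n = np.where(x >= 0.6, 1.0, 0.0)
        assert penetration_depth(n, 2.0, fgrid) == pytest.approx(0.4, abs=fgrid.h)

    def test_linear_front_interpolated(self, fgrid):
        # n = x crosses theta=0.5 exactly at x=0.5; interpolation is exact
        x = np.linspace(0, 1, fgrid.n_filter_nodes)
        assert penetration_depth(x, 2.0, fgrid) == pytest.approx(0.5, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n0a=st.floats(1.5, 1e6), factor=st.floats(1.0, 1e3),
           seed=st.integers(0, 100))
    def test_monotone_in_threshold(self, fgrid, n0a, factor, seed):
        """Raising n0 (lowering the detection threshold) never decreases H."""
        rng = np.random.default_rng(seed)
        n = rng.uniform(0, 1, fgrid.n_filter_nodes)
        assert (penetration_depth(n, n0a * factor, fgrid)
                >= penetration_depth(n, n0a, fgrid) - 1e-12)


class TestPercentChange:
    def test_definitional(self):
        assert percent_change(100.0, 185.19) == pytest.approx(85.19)
        assert percent_change(200.0, 161.08) == pytest.approx(-19.46)
        assert percent_change(7.0, 7.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestUnimodalArgmax:
    def test_symmetric_parabola(self):
        xs = np.arange(7.0)
        ys = -(xs - 3.0) ** 2
        assert find_unimodal_argmax(xs, ys) == pytest.approx(3.0)

    def test_monotone_reports_no_interior_maximum(self):
        xs = np.arange(5.0)
        with pytest.raises(ValueError, match="no interior maximum"):
            find_unimodal_argmax(xs, xs ** 2)

    def test_golden_section_refinement(self):
        f = lambda x: -(x - 2.3456789) ** 2  # noqa: E731
        xs = np.arange(6.0)
        ys = np.array([f(x) for x in xs])
        x_star = find_unimodal_argmax(xs, ys, f=f, xtol=1e-8)
        assert x_star == pytest.approx(2.3456789, abs=1e-7)

    def test_requires_enough_points(self):
        with pytest.raises(ValueError):
            find_unimodal_argmax([0, 1], [0, 1])


def test_fl1h_rescale():
    assert fl1h_rescale(2.258e-8) == pytest.approx(22.58)
    assert fl1h_rescale(1.8e-8) == pytest.approx(18.0)
    assert fl1h_rescale(0.0) == 0.0
    with pytest.raises(ValueError):
        fl1h_rescale(-1.0)


def test_summary_invariants():
    MigrationSummary(N_f=10.0, H=0.5, t=5.0)
    with pytest.raises(ValueError):
        MigrationSummary(N_f=-1.0, H=0.5, t=5.0)
    with pytest.raises(ValueError):
        MigrationSummary(N_f=1.0, H=1.5, t=5.0)


class TestSweep:
    def test_single_row_matches_direct_simulation(self, params, coarse):
        from decoychemo import simulate, sweep_c0

        tab = sweep_c0(params, [params.c0], t_max=0.2, **coarse)
        direct = simulate(params, t_max=0.2, snapshot_times=(0.2,), **coarse)
        assert tab.loc[0, "N_f"] == pytest.approx(direct.migrated_count())
        assert tab.loc[0, "H"] == pytest.approx(direct.penetration_depth())
        assert tab.loc[0, "status"].startswith("ok")

    def test_c0_enters_scalings_per_row(self, params):
        """Doubling c0 doubles the binding rates and halves the receptor loads."""
        from decoychemo import nondimensionalize

        d1 = nondimensionalize(params)
        d2 = nondimensionalize(params.replace(c0=2 * params.c0))
        assert d2.k_a1 == pytest.approx(2 * d1.k_a1)
        assert d2.k_a2 == pytest.approx(2 * d1.k_a2)
        assert d2.Gamma_r == pytest.approx(d1.Gamma_r / 2)
        assert d2.Gamma_d == pytest.approx(d1.Gamma_d / 2)

    def test_failed_row_isolated(self, params, coarse):
        from decoychemo import sweep_c0

        with pytest.raises(ValueError):
            sweep_c0(params, [-1e-8], t_max=0.1, **coarse)
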