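"""Pennes bioheat solver: closed-form validation, conservation, 2D consistency."""

import numpy as np
import pytest

from ocutherm import bioheat as bh
from ocutherm.bioheat import (
    BoundarySpec,
    Geometry1D,
    SourceField,
    TissueLayer,
    boundary_flux,
    calibrate_source,
    decay_regime_metrics,
    heat_source_from_pressure,
    solve_bioheat_1d,
    solve_bioheat_2d,
    steady_state_1d,
)


@pytest.fixture
def slab_geom():
    """Single 10 mm conductive slab, both ends clamped to 33 degC."""
    layer = TissueLayer(name="slab", thickness=10e-3, k_cond=0.58, T_a=33.0)
    return Geometry1D([layer], dz=5e-5)


@pytest.fixture
def slab_bc():
    return BoundarySpec(anterior_fixed_T=33.0, far_boundary="fixed_core_temperature")


class TestBoundaryFlux:
    def test_zero_at_ambient(self):
        bc = BoundarySpec()
        assert boundary_flux(30.0, bc) == 0.0

    def test_hand_computed_value(self):
        bc = BoundarySpec(h_c=14.0, T_amb=30.0, emissivity=0.975)
        quartic = (35.0 + 273.15) ** 4 - (30.0 + 273.15) ** 4
        expect = 14.0 * 5.0 + 0.975 * bc.sigma_SB * quartic
        assert boundary_flux(35.0, bc) == pytest.approx(expect, rel=1e-12)

    def test_strictly_increasing_in_surface_temperature(self):
        bc = BoundarySpec()
        T = np.linspace(20.0, 45.0, 100)
        assert np.all(np.diff(boundary_flux(T, bc)) > 0)


class TestHeatSource:
    def test_hand_value(self):
        geom = Geometry1D(
            [TissueLayer(name="m", thickness=1e-2, rho_t=1000.0, alpha_abs=5.0,
                         c_sound=1500.0)],
            dz=1e-3,
        )
        src = heat_source_from_pressure(np.full(geom.n_nodes, 100e3), geom, duty=1.0)
        # H = alpha p^2 / (rho c) = 5e10/1.5e6, equivalently 2 alpha I
        I = (100e3) ** 2 / (2 * 1000.0 * 1500.0)
        assert np.allclose(src.H, 2 * 5.0 * I)
        assert np.allclose(src.H, 33333.333, rtol=1e-6)

    def test_zero_pressure_and_quadratic_scaling(self):
        geom = Geometry1D([TissueLayer(name="m", thickness=1e-2, alpha_abs=5.0)], dz=1e-3)
        p = np.zeros(geom.n_nodes)
        p[3] = 2e4
        s1 = heat_source_from_pressure(p, geom)
        s2 = heat_source_from_pressure(2 * p, geom)
        assert s1.H[0] == 0.0
        assert s2.H[3] == pytest.approx(4 * s1.H[3])

    def test_grid_mismatch_rejected(self):
        geom = Geometry1D([TissueLayer(name="m", thickness=1e-2)], dz=1e-3)
        with pytest.raises(ValueError, match="does not match"):
            heat_source_from_pressure(np.ones(geom.n_nodes + 3), geom)


class TestSolver1D:
    def test_equilibrium_is_preserved(self):
        geom = Geometry1D([TissueLayer(name="s", thickness=5e-3, T_a=30.0)], dz=1e-4)
        bc = BoundarySpec(h_c=14.0, T_amb=30.0, far_boundary="fixed_core_temperature")
        T0 = np.full(geom.n_nodes, 30.0)
        for scheme in ("implicit", "explicit"):
            fld = solve_bioheat_1d(
                geom, SourceField(H=np.zeros(geom.n_nodes)), bc,
                dt=5e-3, t_end=0.5, T_init=T0, scheme=scheme,
            )
            assert np.max(np.abs(fld.T[-1] - 30.0)) < 1e-10

    def test_steady_slab_matches_parabola(self, slab_geom, slab_bc):
        """Constant H between equal fixed ends: dT = H x (L - x) / 2k."""
        H, L, k = 1000.0, 10e-3, 0.58
        src = SourceField(H=np.full(slab_geom.n_nodes, H))
        dT = steady_state_1d(slab_geom, slab_bc, src=src) - steady_state_1d(slab_geom, slab_bc)
        x = slab_geom.z
        exact = H * x * (L - x) / (2 * k)
        assert abs(dT.max() - 0.02155) < 1e-4
        assert np.max(np.abs(dT - exact)) / exact.max() < 0.01

    def test_transient_reaches_steady_parabola(self, slab_geom, slab_bc):
        H = 1000.0
        src = SourceField(H=np.full(slab_geom.n_nodes, H))
        fld = solve_bioheat_1d(slab_geom, src, slab_bc, dt=10.0, t_end=3000.0)
        exact_peak = H * (10e-3) ** 2 / (8 * 0.58)
        assert fld.final_delta_T.max() == pytest.approx(exact_peak, rel=0.01)

    def test_perfusion_relaxation_rate(self):
        """k -> 0, H = 0: uniform T relaxes to T_a at rate Wb Cpb / (rho Ct)."""
        lay = TissueLayer(name="p", thickness=5e-3, k_cond=1e-6, W_b=2.0,
                          C_pb=3840.0, T_a=37.0)
        geom = Geometry1D([lay], dz=2.5e-4)
        bc = BoundarySpec(h_c=0.0, emissivity=0.0, far_boundary="insulated")
        rate = lay.W_b * lay.C_pb / (lay.rho_t * lay.C_t)
        t_end = 50.0
        fld = solve_bioheat_1d(
            geom, SourceField(H=np.zeros(geom.n_nodes)), bc, dt=0.01, t_end=t_end,
            T_init=np.full(geom.n_nodes, 30.0), scheme="explicit",
        )
        exact = 37.0 + (30.0 - 37.0) * np.exp(-rate * t_end)
        assert fld.T[-1][geom.n_nodes // 2] == pytest.approx(exact, abs=1e-4)

    def test_explicit_unstable_dt_rejected_with_bound(self):
        geom = Geometry1D([TissueLayer(name="s", thickness=5e-3)], dz=1e-4)
        bc = BoundarySpec()
        with pytest.raises(ValueError, match="stability"):
            solve_bioheat_1d(geom, SourceField(H=np.zeros(geom.n_nodes)), bc,
                             dt=1.0, t_end=10.0, scheme="explicit")

    def test_energy_balance_insulated(self):
        """Insulated, no perfusion: dE/dt equals the injected power each step."""
        geom = Geometry1D([TissueLayer(name="e", thickness=10e-3)], dz=2e-4)
        bc = BoundarySpec(h_c=0.0, emissivity=0.0, far_boundary="insulated")
        rng = np.random.default_rng(7)
        H = rng.uniform(0, 5e4, geom.n_nodes)
        dt = 0.004
        fld = solve_bioheat_1d(geom, SourceField(H=H), bc, dt=dt, t_end=1.0,
                               T_init=np.full(geom.n_nodes, 33.0),
                               scheme="explicit", store_every=1)
        V = geom.node_volumes()
        cap = geom.node_property("rho_t") * geom.node_property("C_t") * V
        E = (cap * fld.T).sum(axis=1)
        P_in = (H * V).sum()
        assert np.max(np.abs(np.diff(E) / dt - P_in)) / P_in < 0.005

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_discrete_maximum_principle(self, seed):
        """Source-free evolution never leaves the initial/boundary range."""
        rng = np.random.default_rng(seed)
        lay = TissueLayer(name="m", thickness=8e-3, T_a=33.0)
        geom = Geometry1D([lay], dz=2e-4)
        bc = BoundarySpec(anterior_fixed_T=33.0, far_boundary="fixed_core_temperature")
        T0 = rng.uniform(30.0, 37.0, geom.n_nodes)
        lo, hi = min(T0.min(), 33.0), max(T0.max(), 33.0)
        fld = solve_bioheat_1d(geom, SourceField(H=np.zeros(geom.n_nodes)), bc,
                               dt=5e-3, t_end=1.0, T_init=T0, scheme="explicit",
                               store_every=1)
        assert fld.T.min() >= lo - 1e-9
        assert fld.T.max() <= hi + 1e-9

    def test_delta_T_nonnegative_from_equilibrium(self):
        layers = [TissueLayer(name="a", thickness=6e-3, alpha_abs=5.0),
                  TissueLayer(name="b", thickness=6e-3, k_cond=0.4)]
        geom = Geometry1D(layers, dz=2e-4)
        bc = BoundarySpec()
        H = np.abs(np.sin(geom.z * 800)) * 2e4
        fld = solve_bioheat_1d(geom, SourceField(H=H), bc, dt=0.5, t_end=20.0)
        assert fld.delta_T.min() >= -1e-10

    def test_grid_convergence(self):
        """Halving dz changes the final temperature-rise profile < 1%."""
        def run(dz):
            layers = [
                TissueLayer(name="saline", thickness=28e-3, rho_t=1000.0, C_t=4180.0,
                            k_cond=0.60, alpha_abs=30.0),
                TissueLayer(name="cornea", thickness=0.55e-3, C_t=4178.0,
                            k_cond=0.58, alpha_abs=60.0),
                TissueLayer(name="aqueous", thickness=3.05e-3, rho_t=996.0,
                            C_t=3997.0, k_cond=0.58, alpha_abs=3.0),
            ]
            geom = Geometry1D(layers, dz=dz)
            bc = BoundarySpec()
            p = 1e5 * np.exp(-30.0 * geom.z)
            src = heat_source_from_pressure(p, geom, duty=0.4)
            fld = solve_bioheat_1d(geom, src, bc, dt=1.0, t_end=30.0)
            return geom.z, fld.final_delta_T

        z1, d1 = run(2e-4)
        z2, d2 = run(1e-4)
        interp = np.interp(z1, z2, d2)
        assert np.max(np.abs(d1 - interp)) / interp.max() < 0.01

    def test_nonuniform_source_grid_rejected(self, slab_geom, slab_bc):
        with pytest.raises(ValueError, match="source grid"):
            solve_bioheat_1d(slab_geom, SourceField(H=np.zeros(3)), slab_bc,
                             dt=1.0, t_end=10.0)


class TestSolver2D:
    def _geom(self):
        layers = [TissueLayer(name="a", thickness=6e-3, alpha_abs=5.0),
                  TissueLayer(name="b", thickness=4e-3, k_cond=0.4, C_t=3000.0)]
        return Geometry1D(layers, dz=2e-4)

    def test_uniform_source_matches_1d(self):
        geom = self._geom()
        bc = BoundarySpec()
        H1 = np.abs(np.sin(geom.z * 500)) * 5e4
        f1 = solve_bioheat_1d(geom, SourceField(H=H1), bc, dt=1.0, t_end=30.0)
        r = np.linspace(0, 4e-3, 9)
        f2 = solve_bioheat_2d(geom, np.tile(H1, (9, 1)), bc, dt=1.0, t_end=30.0, r_grid=r)
        d1, d2 = f1.final_delta_T, f2.final_delta_T
        assert np.max(np.abs(d2[0] - d1)) / d1.max() < 0.01

    def test_zero_source_stays_at_equilibrium(self):
        geom = self._geom()
        bc = BoundarySpec()
        r = np.linspace(0, 3e-3, 5)
        fld = solve_bioheat_2d(geom, np.zeros((5, geom.n_nodes)), bc,
                               dt=1.0, t_end=10.0, r_grid=r)
        assert np.max(np.abs(fld.final_delta_T)) < 1e-9

    def test_hotspot_in_saline_when_proximal_deposition_dominates(self):
        """Deposition concentrated next to the source face puts the rise there."""
        layers = [TissueLayer(name="saline", thickness=28e-3, rho_t=1000.0,
                              C_t=4180.0, k_cond=0.6, alpha_abs=30.0),
                  TissueLayer(name="cornea", thickness=0.55e-3, alpha_abs=60.0),
                  TissueLayer(name="aqueous", thickness=5e-3, alpha_abs=3.0)]
        geom = Geometry1D(layers, dz=4e-4)
        bc = BoundarySpec()
        r = np.linspace(0, 5e-3, 6)
        p = 1e5 * np.exp(-30.0 * geom.z)  # decaying from the face
        H1 = heat_source_from_pressure(p, geom, duty=0.4).H
        fld = solve_bioheat_2d(geom, np.tile(H1, (6, 1)), bc, dt=2.0, t_end=60.0, r_grid=r)
        i, j = np.unravel_index(np.argmax(fld.final_delta_T), fld.final_delta_T.shape)
        assert geom.z[j] < 28e-3  # inside the saline
        assert geom.z[j] < 5e-3  # adjacent to the face

    def test_bad_grids_rejected(self):
        geom = self._geom()
        bc = BoundarySpec()
        with pytest.raises(ValueError, match="shape"):
            solve_bioheat_2d(geom, np.zeros((3, 4)), bc, dt=1.0, t_end=5.0,
                             r_grid=np.linspace(0, 1e-3, 3))
        with pytest.raises(ValueError, match="r_grid"):
            solve_bioheat_2d(geom, np.zeros((3, geom.n_nodes)), bc, dt=1.0,
                             t_end=5.0, r_grid=np.array([1e-3, 2e-3, 3e-3]))


class TestDecayMetrics:
    def test_piecewise_exponential_recovered_exactly(self):
        z = np.linspace(0, 50e-3, 501)
        b1, b2, zb = 40.0, 200.0, 28e-3
        dT = np.where(z <= zb, np.exp(-b1 * z), np.exp(-b1 * zb - b2 * (z - zb)))
        rates = decay_regime_metrics(z, dT, z_break=zb,
                                     pre_window=(0.0, zb), post_window=(zb, 50e-3))
        assert rates["rate_pre_cornea"] == pytest.approx(b1, rel=1e-9)
        assert rates["rate_post_cornea"] == pytest.approx(b2, rel=1e-9)

    def test_flat_profile_gives_zero_rates(self):
        z = np.linspace(0, 10e-3, 50)
        rates = decay_regime_metrics(z, np.full(50, 0.3), z_break=5e-3)
        assert rates["rate_pre_cornea"] == pytest.approx(0.0, abs=1e-9)
        assert rates["rate_post_cornea"] == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_window_rejected(self):
        z = np.linspace(0, 10e-3, 50)
        dT = np.linspace(1.0, -0.1, 50)
        with pytest.raises(ValueError, match="non-positive"):
            decay_regime_metrics(z, dT, z_break=5e-3)


class TestCalibration:
    def _setup(self):
        layers = [TissueLayer(name="a", thickness=10e-3, alpha_abs=10.0)]
        geom = Geometry1D(layers, dz=2e-4)
        bc = BoundarySpec()
        src = heat_source_from_pressure(1e5 * np.exp(-10 * geom.z), geom, duty=0.4)
        return geom, src, bc

    def test_self_target_gives_unit_scale(self):
        geom, src, bc = self._setup()
        base = solve_bioheat_1d(geom, src, bc, dt=1.0, t_end=20.0)
        peak = float(np.max(base.final_delta_T))
        cal = calibrate_source(peak, geom, src, bc, dt=1.0, t_end=20.0, free="alpha_scale")
        assert cal["h_scale"] == pytest.approx(1.0, rel=1e-3)

    def test_alpha_scale_linearity(self):
        geom, src, bc = self._setup()
        c1 = calibrate_source(0.1, geom, src, bc, dt=1.0, t_end=20.0, free="alpha_scale")
        c2 = calibrate_source(0.2, geom, src, bc, dt=1.0, t_end=20.0, free="alpha_scale")
        assert c2["h_scale"] == pytest.approx(2 * c1["h_scale"], rel=1e-2)
        assert np.allclose(c2["source"].H, 2 * c1["source"].H, rtol=1e-2)
        assert c1["peak_delta_T"] == pytest.approx(0.1, rel=1e-3)

    def test_v0_free_returns_sqrt_of_h_scale(self):
        geom, src, bc = self._setup()
        cal = calibrate_source(0.5, geom, src, bc, dt=1.0, t_end=20.0, free="v0")
        assert cal["scale_factor"] == pytest.approx(np.sqrt(cal["h_scale"]), rel=1e-12)

    def test_zero_baseline_rejected(self):
        geom, _, bc = self._setup()
        src0 = SourceField(H=np.zeros(geom.n_nodes))
        with pytest.raises(ValueError, match="no positive|deposits no heat"):
            calibrate_source(0.5, geom, src0, bc, dt=1.0, t_end=5.0)


class TestTypes:
    def test_layer_invariants(self):
        with pytest.raises(ValueError):
            TissueLayer(name="x", thickness=0.0)
        with pytest.raises(ValueError):
            TissueLayer(name="x", thickness=1e-3, k_cond=-1.0)
        with pytest.raises(ValueError):
            TissueLayer(name="x", thickness=1e-3, alpha_abs=-0.1)

    def test_geometry_resolves_thin_layers(self):
        geom = Geometry1D(
            [TissueLayer(name="thick", thickness=10e-3),
             TissueLayer(name="thin", thickness=0.5e-3)],
            dz=1e-3,
        )
        # the thin layer still carries at least 5 nodes (4 cells)
        edges = np.isclose(geom.z, 10e-3) | (geom.z > 10e-3)
        assert edges.sum() >= 5
        assert geom.total_length == pytest.approx(10.5e-3)

    def test_negative_source_rejected(self):
        with pytest.raises(ValueError):
            SourceField(H=np.array([1.0, -2.0]))

    def test_bad_duty_rejected(self):
        with pytest.raises(ValueError):
            SourceField(H=np.ones(3), duty=1.5)
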