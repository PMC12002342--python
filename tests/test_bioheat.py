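"""Bioheat solver verification: domain construction, equilibrium preservation,
the closed-form perfusion-relaxation ODE, an independent two-region
modified-Bessel steady-state oracle, energy bookkeeping, and probe
interpolation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import iv, kv

from mnph.bioheat import (
    BloodProperties,
    PennesBioheatModel,
    SimulationGrid,
    TemperatureHistory,
    TissueMaterial,
    TissueModel,
    default_probe_points,
    extract_probes,
    perfusion_source,
    simulate,
    steady_state_estimate,
)
from mnph.constants import T_BODY
from mnph.scenario import default_scenario

from _helpers import uniform_model

COARSE = SimulationGrid(dr=1e-3, dz=1e-3, dt=4.0, duration=1200.0)


class TestDomainConstruction:
    def test_tumor_spans_ten_radial_cells(self):
        model = default_scenario()
        solver = PennesBioheatModel(model, SimulationGrid(dr=0.5e-3, dz=0.5e-3))
        # nodes at r = 0 .. 5 mm inclusive: 10 cell widths, 11 nodes
        assert int(solver.tumor_mask_r.sum()) == 11

    def test_equal_radii_rejected(self):
        with pytest.raises(ValueError):
            replace(default_scenario(), tumor_radius=15e-3)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            PennesBioheatModel(default_scenario(), SimulationGrid(dr=2.5e-3, dz=2.5e-3))

    def test_cell_volumes_conserve_cylinder_volume(self):
        model = default_scenario()
        solver = PennesBioheatModel(model, SimulationGrid(dr=0.5e-3, dz=0.5e-3))
        V = solver.cell_volumes()
        total = math.pi * model.skin_radius**2 * model.height
        assert V.sum() == pytest.approx(total, rel=1e-12)
        tumor_exact = math.pi * model.tumor_radius**2 * model.height
        one_layer = 2 * math.pi * model.tumor_radius * 0.5e-3 * model.height
        assert abs(V[solver.tumor_mask].sum() - tumor_exact) <= one_layer


class TestPerfusionSource:
    def test_zero_at_arterial_temperature(self):
        model = default_scenario()
        assert perfusion_source(model.blood.T_b, model.tumor, model.blood) == 0.0

    def test_reference_magnitude(self):
        # one kelvin above arterial blood with tumor perfusion
        model = default_scenario()
        q = perfusion_source(model.blood.T_b + 1.0, model.tumor, model.blood)
        assert q == pytest.approx(-5.0891e4, rel=1e-4)

    def test_linearity(self):
        model = default_scenario()
        dT = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        q = perfusion_source(model.blood.T_b + dT, model.tumor, model.blood)
        np.testing.assert_allclose(q, -dT * 5.08912e4, rtol=1e-4)


class TestStepping:
    def test_equilibrium_preserved(self):
        # no sources, uniform T = T_b, insulated: the state is a fixed point
        model = uniform_model()
        solver = PennesBioheatModel(model, COARSE)
        T = np.full(solver.n_r * solver.n_z, model.blood.T_b)
        T_new = solver.step(T)
        assert np.max(np.abs(T_new - T)) < 1e-12

    def test_uniform_perfusion_relaxation_matches_ode(self):
        # uniform initial excess decays as T_b + 8 exp(-t/tau), tau = rho C_p/(rho_b C_b w_b)
        model = uniform_model(T_0=273.15 + 45.0)
        tau = 1090.0 * 3421.0 / (1050.0 * 3617.0 * 1.34e-2)
        assert tau == pytest.approx(73.2718, rel=1e-4)
        grid = SimulationGrid(dr=1e-3, dz=1e-3, dt=0.1, duration=200.0, theta=0.5)
        hist = simulate(model, grid)
        t = hist.probe_times
        expected = model.blood.T_b + 8.0 * np.exp(-t / tau)
        np.testing.assert_allclose(hist.probe_values[:, 0], expected, rtol=1e-4)
        # spot value at t ~ tau
        i = int(np.argmin(np.abs(t - tau)))
        assert hist.probe_values[i, 0] - 273.15 == pytest.approx(39.943, abs=0.005)

    def test_halving_dt_leaves_steady_solution_unchanged(self):
        model = default_scenario()
        peaks = []
        for dt in (8.0, 4.0):
            grid = SimulationGrid(dr=1e-3, dz=1e-3, dt=dt, duration=3600.0)
            peaks.append(simulate(model, grid).peak())
        assert abs(peaks[0] - peaks[1]) < 1e-3

    def test_energy_bookkeeping(self):
        model = default_scenario()
        solver = PennesBioheatModel(model, COARSE)
        T = np.full(solver.n_r * solver.n_z, model.T_0)
        for _ in range(3):
            T_new = solver.step(T)
            assert solver.energy_residual(T, T_new) < 1e-6
            T = T_new


class TestSimulate:
    def test_relaxes_to_equilibrium_without_sources(self, ):
        model = uniform_model(T_0=273.15 + 45.0)
        grid = SimulationGrid(dr=1e-3, dz=1e-3, dt=4.0, duration=1200.0)
        hist = simulate(model, grid)
        assert np.max(np.abs(hist.fields[-1] - model.blood.T_b)) < 1e-4

    def test_radial_profile_monotone_from_center(self, reference_run):
        r, prof = reference_run.radial_profile()
        assert np.all(np.diff(prof) <= 1e-9)
        # peak sits on the axis; z-variation is roundoff-level (data are z-uniform)
        assert prof[0] == pytest.approx(reference_run.peak(), rel=1e-12)

    def test_peak_below_perfusion_bound(self, reference_run):
        bound = steady_state_estimate(default_scenario())
        assert reference_run.peak() <= bound

    def test_temperature_bounds(self, reference_run):
        model = default_scenario()
        lo = min(model.T_0, model.T_ext, model.blood.T_b) - 1e-9
        assert reference_run.fields.min() >= lo
        assert np.all(np.isfinite(reference_run.fields))

    def test_center_probe_dominates_outer_probe(self, reference_run):
        p = reference_run.probe_values
        assert np.all(p[:, 0] >= p[:, -1] - 1e-12)


class TestSteadyStateEstimate:
    def test_reference_value(self):
        model = default_scenario()
        assert steady_state_estimate(model) - model.blood.T_b == pytest.approx(
            4.4621, abs=1e-3
        )

    def test_no_sources_returns_arterial_temperature(self):
        model = replace(default_scenario(), Q_nano=0.0)
        model = replace(model, tumor=replace(model.tumor, Q_met=0.0))
        assert steady_state_estimate(model) == model.blood.T_b

    def test_zero_perfusion_rejected(self):
        model = default_scenario()
        model = replace(model, tumor=replace(model.tumor, omega_b=0.0))
        with pytest.raises(ValueError):
            steady_state_estimate(model)


def bessel_two_region_center_excess(model):
    """Independent steady-state oracle: infinite two-region cylinder with
    perfusion, uniform sources, and a Robin condition at the outer radius.
    Valid for the nested-cylinder scenario because insulated end faces and
    z-independent data make the solution z-independent."""
    a, b = model.tumor_radius, model.skin_radius
    k1, k2 = model.tumor.k, model.skin.k
    pb = model.blood.rho_b * model.blood.C_b
    P1, P2 = pb * model.tumor.omega_b, pb * model.skin.omega_b
    S1 = model.Q_nano + model.tumor.Q_met
    S2 = model.skin.Q_met
    L1, L2 = math.sqrt(k1 / P1), math.sqrt(k2 / P2)
    t1, t2 = S1 / P1, S2 / P2
    h = model.h
    M = np.array(
        [
            [iv(0, a / L1), -iv(0, a / L2), -kv(0, a / L2)],
            [k1 * iv(1, a / L1) / L1, -k2 * iv(1, a / L2) / L2, k2 * kv(1, a / L2) / L2],
            [
                0.0,
                -k2 * iv(1, b / L2) / L2 - h * iv(0, b / L2),
                k2 * kv(1, b / L2) / L2 - h * kv(0, b / L2),
            ],
        ]
    )
    rhs = np.array([t2 - t1, 0.0, h * t2])
    A, _, _ = np.linalg.solve(M, rhs)
    return t1 + A


def test_steady_state_matches_bessel_oracle():
    """The converged PDE steady state reproduces the analytic two-region
    modified-Bessel solution at the tumor center."""
    model = default_scenario()
    expected = model.blood.T_b + bessel_two_region_center_excess(model)
    grid = SimulationGrid(dr=0.25e-3, dz=3e-3, dt=5.0, duration=3600.0)
    hist = simulate(model, grid)
    center = hist.fields[-1][0, len(hist.z) // 2]
    assert center == pytest.approx(expected, abs=0.05)


class TestProbes:
    def test_default_probe_layout(self):
        model = default_scenario()
        pts = default_probe_points(model)
        assert pts.shape == (6, 2)
        np.testing.assert_allclose(pts[:, 1], model.height / 2)
        np.testing.assert_allclose(np.diff(pts[:, 0]), model.skin_radius / 5)

    def test_probe_at_grid_node_returns_nodal_value(self, reference_run):
        h = reference_run
        i, j = 4, 10
        interp = h.interpolator(-1)
        val = interp([[h.r[i], h.z[j]]])[0]
        assert val == pytest.approx(h.fields[-1][i, j], rel=1e-12)

    def test_bilinear_midpoint_identity(self):
        # for a bilinear field the cell-midpoint value is the 4-corner mean
        r = np.linspace(0, 1e-2, 11)
        z = np.linspace(0, 2e-2, 21)
        f = 300.0 + 5.0 * r[:, None] / 1e-2 + 3.0 * z[None, :] / 2e-2
        hist = TemperatureHistory(
            r=r, z=z, times=np.array([0.0]), fields=f[None],
            probe_times=np.array([0.0]), probe_values=np.zeros((1, 1)),
            probe_points=np.zeros((1, 2)), probe_names=("P1",),
        )
        interp = hist.interpolator(0)
        mid = interp([[r[3] + (r[4] - r[3]) / 2, z[7] + (z[8] - z[7]) / 2]])[0]
        corners = (f[3, 7] + f[4, 7] + f[3, 8] + f[4, 8]) / 4
        assert mid == pytest.approx(corners, rel=1e-12)

    def test_out_of_domain_probe_rejected(self):
        model = default_scenario()
        solver = PennesBioheatModel(model, COARSE)
        with pytest.raises(ValueError, match="outside"):
            solver.solve(probe_points=[[0.02, 0.015]])

    def test_extract_probes_dataframe(self, reference_run):
        df = extract_probes(reference_run, [[0.0, 0.015], [0.005, 0.015]])
        assert list(df.columns) == ["time_s", "P1", "P2"]
        assert len(df) == len(reference_run.times)
        assert (df["P1"] >= df["P2"] - 1e-9).all()
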