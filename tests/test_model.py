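import numpy as np
import pytest

from h2o2bcr import model
from h2o2bcr.patterns import InputPattern


def rk4_integrate(cells, pattern, t_end, dt):
    """Independent fixed-step RK4 integrator written directly from the
    cascade rate equations (oracle for the adaptive solver)."""
    p = cells.base
    KM1, KM2, KM3 = cells.K_M1, cells.K_M2, cells.K_M3
    KM4, KM5, KM6 = cells.K_M4, cells.K_M5, cells.K_M6
    kros = cells.k_ros

    def f(t, y):
        X, Y, Z = y
        S = pattern.concentration(t)
        P = 1.0 / (1.0 + (S / kros) ** p.H_ros)
        fX, fY, fZ = p.X_T - X, p.Y_T - Y, p.Z_T - Z
        dX = p.k_f * fX / (KM1 + fX) - p.k_r * P * X / (KM2 + X)
        fb = p.k_cat * fY / (p.k_pos + fY)
        if p.feedback_includes_yp:
            fb = fb * Y
        dY = p.k_f * X * fY / (KM3 + fY) + fb - p.k_r * P * Y / (KM4 + Y)
        dZ = p.k_f * Y * fZ / (KM5 + fZ) - p.k_r * P * Z / (KM6 + Z)
        return np.array([dX, dY, dZ])

    y = np.zeros((3, cells.n_cells))
    t = 0.0
    for _ in range(int(round(t_end / dt))):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y.T  # (n_cells, 3)


class TestParameters:
    def test_defaults_match_reference_table(self, params):
        assert (params.k_f, params.k_r) == (1.0, 10.0)
        assert (params.K_M1, params.K_M3, params.K_M5) == (2.0, 0.5, 0.125)
        assert (params.K_M2, params.K_M4, params.K_M6) == (1.0, 1.0, 1.0)
        assert (params.k_cat, params.k_pos, params.k_ros) == (1.0, 1.0, 0.5)
        assert params.H_ros == 1.0
        assert params.s_x50 == 1.25

    def test_validation(self):
        with pytest.raises(ValueError):
            model.ModelParameters(k_f=0.0)
        with pytest.raises(ValueError):
            model.ModelParameters(X_T=1.5)
        with pytest.raises(ValueError):
            model.ModelParameters(s_x50=-0.1)

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.replace(k_ros=0.7).to_yaml(path)
        back = model.ModelParameters.from_yaml(path)
        assert back.k_ros == 0.7
        assert back == params.replace(k_ros=0.7)


class TestPhosphataseActivity:
    def test_known_values(self):
        assert model.phosphatase_activity(0.0, 0.5) == 1.0
        assert model.phosphatase_activity(0.5, 0.5) == 0.5
        assert model.phosphatase_activity(10.0, 0.5, 1.0) == pytest.approx(1 / 21)

    def test_strictly_decreasing(self):
        S = np.linspace(0, 20, 50)
        P = model.phosphatase_activity(S, 0.5, 2.0)
        assert np.all(np.diff(P) < 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            model.phosphatase_activity(-1.0, 0.5)


class TestDerivatives:
    def test_hand_evaluated_at_origin(self, params):
        cells = model.CellParameters.homogeneous(params)
        d = model.cascade_derivatives(np.zeros(3), 0.0, cells)
        assert d[0] == pytest.approx(1 / 3)   # k_f * X_T / (K_M1 + X_T)
        assert d[1] == pytest.approx(0.5)     # basal SYK feedback as printed
        assert d[2] == pytest.approx(0.0)

    def test_feedback_flag_removes_basal_drive(self, params):
        cells = model.CellParameters.homogeneous(params.replace(feedback_includes_yp=True))
        d = model.cascade_derivatives(np.zeros(3), 0.0, cells)
        assert d[1] == 0.0  # feedback proportional to Y_p vanishes at Y_p = 0

    def test_saturated_state_under_full_inhibition(self, params):
        cells = model.CellParameters.homogeneous(params)
        d = model.cascade_derivatives(np.ones(3), 1e9, cells)
        assert d[0] == pytest.approx(0.0, abs=1e-8)

    def test_out_of_bounds_state_rejected(self, params):
        cells = model.CellParameters.homogeneous(params)
        with pytest.raises(ValueError):
            model.cascade_derivatives(np.array([1.5, 0.0, 0.0]), 0.0, cells)


class TestSimulateCell:
    def test_basal_trajectory_reaches_algebraic_steady_state(self, params):
        cells = model.CellParameters.homogeneous(params)
        traj = model.simulate_cell(cells, InputPattern("constant-zero"),
                                   np.linspace(0, 200, 9))
        expected = model.steady_state(cells, 0.0)
        np.testing.assert_allclose(traj.levels[:, -1, :], expected, atol=1e-5)

    def test_saturating_step_drives_full_phosphorylation(self, params):
        cells = model.CellParameters.homogeneous(params)
        traj = model.simulate_cell(cells, InputPattern("step", c_max=1e6),
                                   np.linspace(0, 100, 5))
        np.testing.assert_allclose(traj.levels[0, -1], [1, 1, 1], atol=1e-4)

    def test_bounds_invariant(self, params):
        cells = model.sample_population(params, 20, seed=3)
        traj = model.simulate_cell(cells, InputPattern("linear", c_max=10, T=20),
                                   np.linspace(0, 30, 61))
        assert traj.levels.min() >= 0.0
        assert traj.levels.max() <= 1.0 + 1e-9

    def test_matches_rk4_oracle_on_step_input(self, params):
        cells = model.CellParameters.homogeneous(params)
        oracle = rk4_integrate(cells, InputPattern("step", c_max=10.0), 25.0, 1e-3)
        traj = model.simulate_cell(cells, InputPattern("step", c_max=10.0),
                                   np.array([0.0, 25.0]))
        np.testing.assert_allclose(traj.levels[:, -1, :], oracle, atol=1e-4)

    def test_grid_validation(self, params):
        cells = model.CellParameters.homogeneous(params)
        with pytest.raises(ValueError):
            model.simulate_cell(cells, InputPattern("constant-zero"), [1.0, 2.0])
        with pytest.raises(ValueError):
            model.simulate_cell(cells, InputPattern("constant-zero"), [0.0, 0.0])

    def test_tidy_export_shape(self, params):
        cells = model.sample_population(params, 3, seed=0)
        traj = model.simulate_cell(cells, InputPattern("step", c_max=5.0),
                                   np.linspace(0, 5, 6))
        df = traj.to_frame()
        assert len(df) == 3 * 6 * 3
        assert set(df["protein"]) == set(model.PROTEINS)


class TestSamplePopulation:
    def test_zero_variability_is_degenerate(self, params):
        cells = model.sample_population(params.replace(s_x50=0.0), 5, seed=1)
        assert np.all(cells.K_M1 == params.K_M1)
        assert np.all(cells.k_ros == params.k_ros)

    def test_moment_matching(self, params):
        n = 100_000
        cells = model.sample_population(params, n, seed=7)
        for name in ("K_M1", "K_M5", "k_ros"):
            m = getattr(params, name)
            draws = getattr(cells, name)
            assert draws.mean() == pytest.approx(m, rel=0.02)
            # log-draws are exactly normal with the moment-matched parameters,
            # which is a far more stable check than the heavy-tailed sample
            # variance for strongly skewed channels such as K_M5
            sigma2 = np.log1p(params.s_x50**2 / m)
            logs = np.log(draws)
            assert logs.std() == pytest.approx(np.sqrt(sigma2), rel=0.02)
            assert logs.mean() == pytest.approx(np.log(m) - sigma2 / 2, abs=0.02)

    def test_seed_reproducibility(self, params):
        a = model.sample_population(params, 100, seed=42)
        b = model.sample_population(params, 100, seed=42)
        np.testing.assert_array_equal(a.K_M3, b.K_M3)

    def test_all_draws_positive(self, params):
        cells = model.sample_population(params, 10_000, seed=5)
        assert min(getattr(cells, k).min() for k in
                   ("K_M1", "K_M2", "K_M3", "K_M4", "K_M5", "K_M6", "k_ros")) > 0


class TestPercentOn:
    def _traj(self, params, levels, t=(0.0, 1.0)):
        n = levels.shape[0]
        cells = model.CellParameters.homogeneous(params, n)
        lv = np.repeat(levels[:, None, :], len(t), axis=1)
        return model.PopulationTrajectories(np.array(t), lv, cells,
                                            InputPattern("constant-zero"))

    def test_hand_counted_threshold(self, params):
        z = np.array([0.1, 0.2, 0.4, 0.9])
        levels = np.zeros((4, 3))
        levels[:, 2] = z
        traj = self._traj(params, levels)
        assert model.percent_on(traj)["pPLCg2"].iloc[0] == 50.0

    def test_extremes(self, params):
        traj = self._traj(params, np.zeros((5, 3)))
        assert (model.percent_on(traj).to_numpy() == 0.0).all()
        traj = self._traj(params, np.ones((5, 3)))
        assert (model.percent_on(traj).to_numpy() == 100.0).all()

    def test_fraction_validation(self, params):
        traj = self._traj(params, np.zeros((2, 3)))
        with pytest.raises(ValueError):
            model.percent_on(traj, activation_fraction=1.5)


class TestEC50Percent:
    def test_constructed_crossing(self, params):
        # half the cells switch ON exactly when the gradient reaches 4 mM
        pattern = InputPattern("linear", c_max=10.0, T=10.0)
        t = np.linspace(0, 10, 101)
        conc = pattern.concentration(t)
        n = 10
        levels = np.zeros((n, len(t), 3))
        levels[: n // 2, conc >= 4.0, :] = 0.9
        cells = model.CellParameters.homogeneous(params, n)
        traj = model.PopulationTrajectories(t, levels, cells, pattern)
        ec = model.ec50_percent(traj)
        for prot in model.PROTEINS:
            assert ec[prot] == pytest.approx(4.0, abs=0.11)

    def test_never_reached_gives_nan(self, params):
        pattern = InputPattern("linear", c_max=10.0, T=10.0)
        t = np.linspace(0, 10, 11)
        levels = np.zeros((10, len(t), 3))
        levels[:3, :, :] = 0.9  # only 30% ever ON
        cells = model.CellParameters.homogeneous(params, 10)
        traj = model.PopulationTrajectories(t, levels, cells, pattern)
        assert all(np.isnan(v) for v in model.ec50_percent(traj).values())

    def test_midpoint_interpolation_on_step_jump(self):
        # %ON jumping 0 -> 100 between sampled concentrations a and b
        assert model.interp_crossing(np.array([2.0, 4.0]),
                                     np.array([0.0, 100.0]), 50.0) == 3.0

    def test_requires_gradient(self, params):
        cells = model.CellParameters.homogeneous(params, 2)
        traj = model.PopulationTrajectories(
            np.array([0.0, 1.0]), np.zeros((2, 2, 3)), cells, InputPattern("step", c_max=5)
        )
        with pytest.raises(ValueError):
            model.ec50_percent(traj)


class TestSteadyStateMonotonicity:
    def test_plc_steady_state_non_decreasing_in_dose(self, params):
        cells = model.CellParameters.homogeneous(params)
        doses = np.linspace(0, 25, 26)
        z = np.array([model.steady_state(cells, d)[0, 2] for d in doses])
        assert np.all(np.diff(z) >= -1e-9)


class TestRateSweep:
    def test_single_homogeneous_cell_matches_direct_simulation(self, params):
        p0 = params.replace(s_x50=0.0)
        rate = 0.5
        table = model.rate_sweep(p0, [rate], c_final=10.0, n=1, seed=0, n_conc=201)
        pattern = InputPattern("linear", c_max=10.0, T=10.0 / rate)
        t = np.linspace(0, 20.0, 201)
        traj = model.simulate_cell(model.CellParameters.homogeneous(p0), pattern, t)
        conc = pattern.concentration(t)
        for prot in model.PROTEINS:
            j = model.PROTEINS.index(prot)
            direct = model.interp_crossing(conc, 100.0 * (traj.levels[0, :, j] > 0.3), 50.0)
            got = float(table[table.protein == prot].ec50_percent.iloc[0])
            assert got == pytest.approx(direct, abs=0.11)

    def test_rejects_non_positive_rates(self, params):
        with pytest.raises(ValueError):
            model.rate_sweep(params, [0.5, -1.0], n=1)


class TestSolverRobustness:
    def test_percent_on_stable_under_tighter_tolerances(self, params):
        cells = model.sample_population(params, 100, seed=9)
        pattern = InputPattern("step", c_max=5.0)
        t = np.linspace(0, 10, 11)
        loose = model.simulate_cell(cells, pattern, t, rtol=1e-6, atol=1e-9)
        tight = model.simulate_cell(cells, pattern, t, rtol=5e-7, atol=5e-10)
        diff = (model.percent_on(loose) - model.percent_on(tight)).abs().to_numpy()
        assert diff.max() < 0.5
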