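"""Batch / plug-flow / semi-batch integration and observables."""

import numpy as np
import pytest

import chrysokin as ck
from chrysokin.kinetic_core import SPECIES
from chrysokin.reactor import paper_flow_sections


def euler_oracle(initial, params, T, t_end, dt=1e-4):
    """Fixed-step explicit Euler integration, written out from the rate
    equations independently of the package's rhs; cross-checks the stiff
    integrator."""
    rs = ck.rate_constants_at(T, params)
    k0, k1, k2, k3, K = rs.k0, rs.k1, rs.k2, rs.k3, rs.K
    cat0 = params.catalyst.C_cat0
    eda, dmh, mc, ec, dim, tri = (initial.C_EDA, initial.C_DMH, initial.C_MC,
                                  initial.C_EC, initial.C_DIM, initial.C_TRI)
    n = round(t_end / dt)
    for _ in range(n):
        active = K * dmh * (cat0 - mc) / (1.0 + K * dmh)
        r0 = k0 * eda * active
        r1 = k1 * mc * dmh
        r2 = k2 * mc * eda
        r3 = k3 * mc * dim
        eda += dt * (-r0 - r2)
        dmh += dt * (-r1)
        mc += dt * (r0 - r1 - r2 - r3)
        ec += dt * r1
        dim += dt * (r2 - r3)
        tri += dt * r3
    return np.array([eda, dmh, mc, ec, dim, tri])


class TestSimulateBatch:
    def test_no_catalyst_no_turnover(self, standard_initial):
        p = ck.ModelParams().with_catalyst(C_cat0=1e-300)
        traj = ck.simulate_batch(standard_initial, p, 403.15, 60.0,
                                 t_eval=[0.0, 30.0, 60.0])
        assert np.allclose(traj.states, traj.states[:, :1], atol=1e-12)

    def test_complete_conversion_within_one_minute_at_130C(self, traj_130):
        obs = ck.to_observables(traj_130, 0.02, 60.0)
        assert obs.X_EDA >= 0.99

    def test_low_temperature_validation_yield(self, params, standard_initial):
        traj = ck.simulate_batch(standard_initial, params, 333.15, 10800.0)
        obs = ck.to_observables(traj, 0.02, 10800.0)
        assert obs.Y_EC == pytest.approx(0.543, abs=0.05)

    def test_conservation_along_trajectory(self, traj_130):
        # diazo-unit balance within 10x the solver atol (1e-12) x step count
        assert np.max(np.abs(traj_130.balance_residuals())) < 1e-9
        # DMH + EC constant
        dmh_ec = traj_130.states[1] + traj_130.states[3]
        assert np.allclose(dmh_ec, 0.022, atol=1e-9)

    def test_stiff_solver_matches_euler_oracle(self, params, standard_initial):
        traj = ck.simulate_batch(standard_initial, params, 403.15, 10.0)
        oracle = euler_oracle(standard_initial, params, 403.15, 10.0)
        stiff = traj.state_at(10.0).as_array()
        assert np.max(np.abs(stiff - oracle)) < 1e-6

    def test_invalid_t_end_rejected(self, params, standard_initial):
        with pytest.raises(ValueError):
            ck.simulate_batch(standard_initial, params, 403.15, -1.0)

    def test_conversion_and_ec_yield_monotone_in_time(self, traj_130):
        eda = traj_130.states[0]
        ec = traj_130.states[3]
        assert np.all(np.diff(eda) <= 1e-12)
        assert np.all(np.diff(ec) >= -1e-12)

    def test_dimer_rises_to_plateau_then_decays(self, traj_130):
        """DIM peaks in the interior of the 60 s window (competition between
        generation from EDA and consumption to the trimer)."""
        dim = traj_130.states[4]
        i_max = int(np.argmax(dim))
        assert 0 < i_max < len(dim) - 1
        t_max = traj_130.times[i_max]
        assert 2.0 < t_max < 30.0
        assert dim[-1] < dim[i_max]  # slow decrease after the plateau

    def test_concentration_scaling_leaves_yields_nearly_unchanged(self, params):
        """Halving/doubling both reactants at fixed catalyst moves the final
        yields by < 0.05 while speeding conversion up with concentration."""
        base = {}
        t99s = []
        for mult in (0.5, 1.0, 2.0):
            ini = ck.SpeciesState(C_EDA=0.02 * mult, C_DMH=0.022 * mult)
            traj = ck.simulate_batch(ini, params, 403.15, 120.0)
            obs = ck.to_observables(traj, ini.C_EDA, 120.0)
            base[mult] = obs
            t99s.append(ck.time_to_conversion(traj, 0.99))
        for mult in (0.5, 2.0):
            assert abs(base[mult].Y_EC - base[1.0].Y_EC) < 0.05
            assert abs(base[mult].Y_DIM - base[1.0].Y_DIM) < 0.05
        assert t99s[0] > t99s[1] > t99s[2]

    def test_selectivity_decreases_with_temperature(self, params,
                                                    standard_initial):
        """Final EC yield at full conversion is non-increasing 110->140 degC:
        the main step has the lowest activation energy."""
        yields = []
        for T_C in (110.0, 120.0, 130.0, 140.0):
            traj = ck.simulate_batch(standard_initial, params,
                                     ck.celsius_to_kelvin(T_C), 600.0)
            yields.append(ck.to_observables(traj, 0.02, 600.0).Y_EC)
        assert all(a >= b - 1e-9 for a, b in zip(yields, yields[1:]))


class TestResidenceTime:
    def test_simple_ratio(self):
        flow = ck.FlowConfig(sections=(), total_flow_rate_mL_min=10.0,
                             accessory_volume_mL=10.0)
        assert ck.residence_time(flow) == pytest.approx(60.0)

    def test_largest_configuration(self):
        flow = ck.FlowConfig(sections=(), total_flow_rate_mL_min=20.4,
                             accessory_volume_mL=20.4)
        assert ck.residence_time(flow) == pytest.approx(60.0)

    def test_smallest_paper_configuration_is_1p7_mL(self):
        # one 1 mm i.d. x 2 m section plus 0.13 mL accessories
        flow = ck.FlowConfig(
            sections=(ck.TubeSection(inner_diameter_mm=1.0, length_m=2.0),),
            total_flow_rate_mL_min=1.7,
            accessory_volume_mL=0.13,
        )
        assert flow.reactor_volume_mL == pytest.approx(1.7, abs=0.01)
        assert ck.residence_time(flow) == pytest.approx(60.0, rel=0.01)

    def test_full_pipeline_volume_spans_operating_range(self):
        volume = sum(s.volume_mL for s in paper_flow_sections())
        assert 18.0 < volume < 20.5

    def test_zero_flow_rejected(self):
        flow = ck.FlowConfig(sections=(), total_flow_rate_mL_min=0.0,
                             accessory_volume_mL=1.0)
        with pytest.raises(ValueError):
            ck.residence_time(flow)


class TestPlugFlow:
    def test_equals_batch_at_residence_time(self, params, standard_initial):
        flow = ck.FlowConfig(
            sections=(ck.TubeSection(inner_diameter_mm=1.0, length_m=2.0,
                                     count=4),),
            total_flow_rate_mL_min=12.0,
            accessory_volume_mL=0.13,
        )
        tau = ck.residence_time(flow)
        outlet = ck.simulate_plug_flow(standard_initial, params, 403.15, flow)
        traj = ck.simulate_batch(standard_initial, params, 403.15, tau)
        batch = ck.to_observables(traj, 0.02, tau)
        assert outlet.X_EDA == pytest.approx(batch.X_EDA, abs=1e-9)
        assert outlet.Y_EC == pytest.approx(batch.Y_EC, abs=1e-9)

    def test_zero_residence_time_gives_zero_observables(self, params,
                                                        standard_initial):
        flow = ck.FlowConfig(sections=(), total_flow_rate_mL_min=5.0,
                             accessory_volume_mL=0.0)
        outlet = ck.simulate_plug_flow(standard_initial, params, 403.15, flow)
        assert outlet.X_EDA == 0.0 and outlet.Y_EC == 0.0

    def test_micro_flow_yields_at_60s_130C(self, traj_130):
        """EC around 0.2, dimers around 0.3 at the 1 min outlet."""
        obs = ck.to_observables(traj_130, 0.02, 60.0)
        assert obs.Y_EC == pytest.approx(0.2, abs=0.05)
        assert obs.Y_DIM == pytest.approx(0.3, abs=0.1)


class TestSemiBatch:
    def test_batch_mode_matches_simulate_batch(self, params, standard_initial):
        policy = ck.FeedPolicy(mode="batch")
        a = ck.simulate_semi_batch(policy, standard_initial, params, 403.15,
                                   30.0)
        b = ck.simulate_batch(standard_initial, params, 403.15, 30.0)
        assert np.allclose(a.states[:, -1], b.states[:, -1], atol=1e-10)

    def test_instantaneous_dosing_limit_matches_batch(self, params):
        bulk = ck.SpeciesState(C_DMH=0.022)
        policy = ck.FeedPolicy.uniform(C_EDA_total=0.02, C_cat_total=2e-5,
                                       duration_s=1e-3)
        traj = ck.simulate_semi_batch(policy, bulk, params, 333.15, 3600.0)
        batch = ck.simulate_batch(ck.SpeciesState(C_EDA=0.02, C_DMH=0.022),
                                  params, 333.15, 3600.0)
        assert np.allclose(traj.states[:4, -1], batch.states[:4, -1],
                           atol=1e-5)

    def test_zero_dosing_gives_no_products(self, params):
        bulk = ck.SpeciesState(C_DMH=0.022)
        policy = ck.FeedPolicy(mode="semi-batch", segments=(),
                               C_EDA_total=0.0, C_cat_total=0.0)
        traj = ck.simulate_semi_batch(policy, bulk, params, 403.15, 60.0)
        assert np.allclose(traj.states[[0, 3, 4], :], 0.0, atol=1e-15)

    def test_one_hour_dosing_at_60C_close_to_batch(self, params):
        """Uniform 1 h dosing vs all-at-once at 60 degC, 3 h total: the final
        EC yield shifts by less than 0.05 (frozen regression behaviour)."""
        bulk = ck.SpeciesState(C_DMH=0.022)
        policy = ck.FeedPolicy.uniform(C_EDA_total=0.02, C_cat_total=2e-5,
                                       duration_s=3600.0)
        traj = ck.simulate_semi_batch(policy, bulk, params, 333.15, 10800.0)
        fed = ck.to_observables(traj, 0.02, 10800.0)
        batch = ck.simulate_batch(ck.SpeciesState(C_EDA=0.02, C_DMH=0.022),
                                  params, 333.15, 10800.0)
        ref = ck.to_observables(batch, 0.02, 10800.0)
        assert abs(fed.Y_EC - ref.Y_EC) < 0.05

    def test_mass_inconsistent_policy_rejected(self):
        with pytest.raises(ValueError):
            ck.FeedPolicy(mode="semi-batch",
                          segments=((0.0, 10.0, 1e-3, 0.0),),
                          C_EDA_total=0.05, C_cat_total=0.0)


class TestObservables:
    def test_initial_point_all_zero(self, traj_130):
        obs = ck.to_observables(traj_130, 0.02, 0.0)
        assert obs.X_EDA == pytest.approx(0.0, abs=1e-12)
        assert obs.Y_EC == 0.0 and obs.Y_DIM == 0.0

    def test_yield_arithmetic(self):
        traj = ck.Trajectory(
            times=np.array([0.0, 1.0]),
            states=np.array([[0.02, 0.01], [0.022, 0.018], [0, 0],
                             [0, 0.004], [0, 0.006], [0, 0]]),
            T=400.0, initial_state=ck.SpeciesState(C_EDA=0.02, C_DMH=0.022),
            C_EDA0=0.02)
        obs = ck.to_observables(traj, 0.02, 1.0, dim_basis="molecules")
        assert obs.Y_EC == pytest.approx(0.2)
        assert obs.Y_DIM == pytest.approx(0.3)
        eda_basis = ck.to_observables(traj, 0.02, 1.0)
        assert eda_basis.Y_DIM == pytest.approx(0.6)

    def test_invalid_reference_concentration(self, traj_130):
        with pytest.raises(ValueError):
            ck.to_observables(traj_130, 0.0, 1.0)


class TestTimeToConversion:
    def test_zero_threshold(self, traj_130):
        assert ck.time_to_conversion(traj_130, 0.0) == 0.0

    def test_99_percent_within_one_minute_at_130C(self, traj_130):
        t99 = ck.time_to_conversion(traj_130, 0.99)
        assert t99 is not None and t99 <= 60.0

    def test_exponential_decay_closed_form(self):
        """EDA decaying as exp(-0.1 t): threshold 1 - 1/e is hit at t=10."""
        t = np.linspace(0.0, 40.0, 4001)
        eda = 0.02 * np.exp(-0.1 * t)
        states = np.zeros((6, t.size))
        states[0] = eda
        traj = ck.Trajectory(times=t, states=states, T=400.0,
                             initial_state=ck.SpeciesState(C_EDA=0.02),
                             C_EDA0=0.02)
        t_hit = ck.time_to_conversion(traj, 1.0 - np.exp(-1.0))
        assert t_hit == pytest.approx(10.0, abs=0.02)

    def test_unreachable_threshold_returns_none(self, params):
        ini = ck.SpeciesState(C_EDA=0.02, C_DMH=0.022)
        traj = ck.simulate_batch(ini, params, 333.15, 1.0)
        assert ck.time_to_conversion(traj, 0.99) is None


def test_trajectory_csv_export_columns(traj_130, tmp_path):
    df = traj_130.to_dataframe()
    expected = ["time_s"] + [f"C_{s}" for s in SPECIES] + ["X_EDA", "Y_EC",
                                                           "Y_DIM"]
    assert list(df.columns) == expected
    out = tmp_path / "traj.csv"
    df.to_csv(out, index=False)
    assert out.exists()
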