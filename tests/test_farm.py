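"""Farm-scale coupling: ambient-N advection, cycles, annual runs, sizing."""

import numpy as np
import pytest

from ulvafarm import (
    EnvironmentSample,
    FarmConfig,
    FarmState,
    GrowthParameters,
    PumpSetting,
    UnreachableThresholdError,
    environment_step,
    farm_step,
    generate_synthetic_forcing,
    run_cycle,
    run_year,
    seasonal_spec,
    size_farm_to_threshold,
    stream_flow,
)
from ulvafarm.farm import _outlet_n_env
from ulvafarm.forcing import SyntheticForcingSpec
from ulvafarm.reactor import _step_arrays


def _state(n, N_env, N_ext=None, boundary=None, m=0.15, N_int=2.0):
    N_env = np.full(n, N_env, dtype=float) if np.isscalar(N_env) else np.asarray(N_env, float)
    N_ext = N_env.copy() if N_ext is None else np.full(n, N_ext, dtype=float)
    return FarmState(
        m=np.full(n, m), N_int=np.full(n, N_int), N_ext=N_ext,
        N_env=N_env, boundary_N=float(boundary if boundary is not None else N_env[0]),
    )


class TestEnvironmentStep:
    def test_uniform_field_without_pump_is_stationary(self):
        cfg = FarmConfig(n_reactors=4, d=0.0, pump=PumpSetting(0.0))
        state = _state(4, 200.0, boundary=200.0)
        new = environment_step(state, cfg)
        assert new == pytest.approx(np.full(4, 200.0))

    def test_full_dilution_removes_upstream_contribution(self):
        # d = 1 with no pump: every cell relaxes toward zero
        cfg = FarmConfig(n_reactors=3, d=1.0, pump=PumpSetting(0.0))
        state = _state(3, 200.0, boundary=200.0)
        new = environment_step(state, cfg)
        assert np.all(new < 200.0)
        for _ in range(500):
            state = _state(3, new, N_ext=0.0, boundary=200.0)
            new = environment_step(state, cfg)
        assert new == pytest.approx(np.zeros(3), abs=1e-6)

    def test_matches_hand_oracle_three_cells(self):
        # spreadsheet-style hand evaluation of the per-cell update for
        # given Q_s, Q_p, N_ext: explicit pump exchange, then advection
        # toward (1-d)·upstream with the integrating factor (one Courant
        # sub-step here since Q_s·dt/V < 1)
        Q_s, Q_p, d = 900.0, 300.0, 0.1
        cfg = FarmConfig(n_reactors=3, d=d, Q_s=Q_s, pump=PumpSetting(Q_p))
        V = cfg.geometry.volume_l
        N_ext = np.array([10.0, 20.0, 30.0])
        N0 = np.array([250.0, 240.0, 230.0])
        boundary = 260.0
        state = _state(3, N0, boundary=boundary)
        state.N_ext = N_ext
        got = environment_step(state, cfg, dt=1.0)

        pumped = N0 + Q_p * (N_ext - N0) / V
        target = (1 - d) * np.array([boundary, pumped[0], pumped[1]])
        expected = target + (pumped - target) * np.exp(-Q_s / V)
        assert got == pytest.approx(expected, rel=1e-12)

        # and the one-hour update stays consistent with a fine-step
        # forward-Euler integration of the fully coupled balance
        n = N0.copy()
        dt = 1e-4
        for _ in range(10000):
            up = np.concatenate(([boundary], n[:-1]))
            n = n + dt * (Q_s * ((1 - d) * up - n) - Q_p * (n - N_ext)) / V
        assert got == pytest.approx(n, rel=0.05)

    def test_relaxes_to_geometric_steady_profile(self):
        # pump off: the advective fixed point is N*_x = (1-d)^x · boundary
        cfg = FarmConfig(n_reactors=6, d=0.05, pump=PumpSetting(0.0))
        state = _state(6, 300.0, N_ext=50.0, boundary=300.0)
        for _ in range(48):
            state.N_env = environment_step(state, cfg)
        expected = 300.0 * (1 - cfg.d) ** np.arange(1, 7)
        assert state.N_env == pytest.approx(expected, rel=1e-6)

    def test_single_cell_split_update_closed_form(self):
        # cell 0 with constant boundary: pump kick then exponential
        # relaxation toward (1-d)·boundary, independent of sub-step count
        cfg = FarmConfig(n_reactors=1, d=0.0)
        state = _state(1, 100.0, N_ext=40.0, boundary=300.0)
        got = environment_step(state, cfg, dt=1.0)[0]
        Q_s, Q_p = cfg.Q_s, cfg.pump.Q_p
        V = cfg.geometry.volume_l
        pumped = 100.0 + Q_p * (40.0 - 100.0) / V
        expected = 300.0 + (pumped - 300.0) * np.exp(-Q_s / V)
        assert got == pytest.approx(expected, rel=1e-12)


class TestFarmStep:
    def test_single_reactor_equals_manual_composition(self, params):
        cfg = FarmConfig(n_reactors=1, N_env0=250.0)
        state = FarmState.initial(cfg)
        env = EnvironmentSample(T=19.0, S=30.0, I0=700.0, is_light_hour=True)
        new, _ = farm_step(state, cfg, env, params)

        m, q, ext, _ = _step_arrays(
            state.m, state.N_int, state.N_ext, state.N_env, env,
            cfg.pump.Q_p, cfg.geometry, params, 1.0,
        )
        env_field = environment_step(state, cfg)  # start-of-step N_ext
        assert new.m[0] == m[0] and new.N_int[0] == q[0]
        assert new.N_ext[0] == ext[0] and new.N_env[0] == env_field[0]

    def test_downstream_profile_monotone_in_x(self, params, spring_forcing):
        cfg = FarmConfig(n_reactors=5, d=0.0, N_env0=250.0, boundary_N=250.0)
        state, _ = run_cycle(cfg, spring_forcing, params)
        assert np.all(np.diff(state.N_env) <= 1e-9)

    def test_deterministic(self, params, spring_forcing):
        cfg = FarmConfig(n_reactors=3, N_env0=250.0)
        s1, c1 = run_cycle(cfg, spring_forcing, params)
        s2, c2 = run_cycle(cfg, spring_forcing, params)
        assert np.array_equal(s1.m, s2.m) and np.array_equal(s1.N_env, s2.N_env)
        assert c1.total_production == c2.total_production


class TestRunCycle:
    def test_zero_growth_production_is_zero(self, spring_forcing):
        p = GrowthParameters(mu_max=0.0, lambda_20=0.0)
        cfg = FarmConfig(n_reactors=3, N_env0=250.0)
        state, summary = run_cycle(cfg, spring_forcing, p)
        assert summary.total_production == pytest.approx(0.0, abs=1e-9)
        # N removal reduces to quota change only
        expected = (cfg.m0 * (state.N_int - cfg.N_int0)
                    * cfg.geometry.volume_l / 100.0).sum()
        assert summary.total_n_removed == pytest.approx(expected, rel=1e-12)

    def test_totals_are_sums_over_reactors(self, params, spring_forcing):
        cfg = FarmConfig(n_reactors=4, N_env0=250.0)
        _, summary = run_cycle(cfg, spring_forcing, params)
        assert summary.total_production == pytest.approx(summary.production.sum())
        assert summary.total_n_removed == pytest.approx(summary.n_removed.sum())
        area_days = (cfg.geometry.illuminated_area * cfg.n_reactors
                     * cfg.cycle_length)
        assert summary.areal_productivity == pytest.approx(
            summary.total_production / area_days
        )

    def test_short_forcing_rejected(self, params):
        short = generate_synthetic_forcing(SyntheticForcingSpec(), days=3)
        with pytest.raises(ValueError):
            run_cycle(FarmConfig(n_reactors=2), short, params)

    def test_split_run_equals_single_run(self, params, spring_forcing):
        cfg = FarmConfig(n_reactors=3, N_env0=250.0)
        full, _ = run_cycle(cfg, spring_forcing, params)

        half_cfg = cfg.replace(cycle_length=7)
        mid, _ = run_cycle(half_cfg, spring_forcing, params)
        second = spring_forcing.slice_hours(7 * 24, 7 * 24)
        end, _ = run_cycle(half_cfg, second, params, initial=mid)
        for attr in ("m", "N_int", "N_ext", "N_env"):
            assert np.array_equal(getattr(full, attr), getattr(end, attr))

    def test_recorded_table_is_tidy(self, params, spring_forcing):
        cfg = FarmConfig(n_reactors=2, N_env0=250.0, cycle_length=2)
        _, _, table = run_cycle(cfg, spring_forcing, params, record=True)
        assert list(table.columns) == ["time", "x", "m", "N_int", "N_ext", "N_env"]
        assert len(table) == 2 * 24 * 2


class TestRunYear:
    def test_pearson_undefined_for_identical_cycles(self, params):
        # constant forcing: every cycle is identical, zero variance
        spec = SyntheticForcingSpec(T_amp=0.0, day_length_amp=0.0, I_peak_amp=0.0)
        forcing = generate_synthetic_forcing(spec, days=28)
        cfg = FarmConfig(n_reactors=2, N_env0=250.0)
        annual = run_year(cfg, forcing, params)
        assert len(annual.cycles) == 2
        assert np.isnan(annual.pearson_r)

    def test_synthetic_year_production_tracks_sequestration(self, params):
        forcing = generate_synthetic_forcing(
            SyntheticForcingSpec(), start="2021-01-01", days=364
        )
        cfg = FarmConfig(n_reactors=10, d=0.0, N_env0=250.0)
        annual = run_year(cfg, forcing, params)
        assert len(annual.cycles) == 26
        assert annual.pearson_r >= 0.99
        assert annual.total_production == pytest.approx(
            sum(c.total_production for c in annual.cycles)
        )


class TestFarmSizing:
    def test_threshold_already_met_needs_one_reactor(self, params, spring_forcing):
        cfg = FarmConfig(N_env0=250.0)
        assert size_farm_to_threshold(cfg, spring_forcing, params,
                                      threshold=260.0) == 1

    def test_zero_uptake_is_unreachable(self, spring_forcing):
        p = GrowthParameters(V_max=0.0)
        cfg = FarmConfig(N_env0=250.0, boundary_N=250.0)
        with pytest.raises(UnreachableThresholdError):
            size_farm_to_threshold(cfg, spring_forcing, p, threshold=10.0,
                                   max_reactors=64)

    def test_search_equals_linear_scan(self, params, spring_forcing):
        # small case: moderate threshold reached within ~20 reactors
        cfg = FarmConfig(N_env0=250.0, boundary_N=250.0)
        outlet1 = _outlet_n_env(1, cfg, spring_forcing, params)
        threshold = outlet1 - 6.0 * (250.0 - outlet1)  # ~a dozen reactors
        n = size_farm_to_threshold(cfg, spring_forcing, params, threshold)
        scan = next(
            k for k in range(1, n + 2)
            if _outlet_n_env(k, cfg, spring_forcing, params) <= threshold
        )
        assert n == scan
        assert _outlet_n_env(n, cfg, spring_forcing, params) <= threshold
        if n > 1:
            assert _outlet_n_env(n - 1, cfg, spring_forcing, params) > threshold


def test_stream_flow_scales_with_velocity_and_section(geometry):
    q = stream_flow(0.01, geometry, width=1.0)
    assert q == pytest.approx(0.01 * geometry.Z * 3_600_000.0)
    assert stream_flow(0.02, geometry, width=1.0) == pytest.approx(2 * q)
    with pytest.raises(ValueError):
        stream_flow(-0.01, geometry)
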