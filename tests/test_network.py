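"""Ring-network construction, tuning functions, and ODE integration."""

import numpy as np
import pytest
from dataclasses import replace

from ringtae import (
    NetworkParams,
    SolverSettings,
    StimulusEpoch,
    StimulusProtocol,
    connection_profile,
    decode_orientation,
    lgn_drive,
    simulate,
    von_mises_density,
)

from oracles import bessel_i0_series, euler_simulate, von_mises_ref


class TestNetworkParams:
    def test_defaults_are_the_fitted_set(self):
        p = NetworkParams()
        assert (p.tau, p.alpha, p.j_lgn, p.kappa_lgn) == (8.0, 3.88, 11.04, 0.47)
        assert (p.j_cortex, p.r_ie, p.kappa_e, p.kappa_i) == (2.84, 1.24, 1.12, 0.56)
        assert p.n_units == 256

    @pytest.mark.parametrize("field,value", [
        ("tau", 0.0), ("alpha", -1.0), ("j_lgn", 0.0), ("kappa_lgn", -0.1),
        ("j_cortex", 0.0), ("r_ie", -1.0), ("kappa_e", 0.0), ("kappa_i", -2.0),
        ("n_units", 4),
    ])
    def test_invalid_constants_rejected(self, field, value):
        with pytest.raises(ValueError):
            replace(NetworkParams(), **{field: value})

    def test_preferred_orientations_tile_evenly(self):
        p = NetworkParams(n_units=16)
        theta = p.preferred_orientations
        assert theta[0] == 0.0
        assert np.allclose(np.diff(theta), 180.0 / 16)
        assert theta[-1] < 180.0  # no duplicated endpoint


class TestStimulusTypes:
    def test_orientation_reduced_mod_180(self):
        assert StimulusEpoch(200.0).orientation == 20.0
        assert StimulusEpoch(-20.0).orientation == 160.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusEpoch(0.0, duration=0.0)

    def test_protocol_requires_epochs_and_sums_durations(self):
        with pytest.raises(ValueError):
            StimulusProtocol(epochs=())
        proto = StimulusProtocol.adapt_test(20.0, adapter_ms=200, test_ms=300)
        assert proto.total_duration == 500.0


class TestVonMises:
    def test_zero_concentration_is_uniform(self):
        x = np.linspace(-90, 260, 13)
        assert np.allclose(von_mises_density(x, 10.0, 0.0), 1.0 / (2 * np.pi))

    def test_peak_value_matches_series_oracle(self):
        # f(mu | mu, 1) = e / (2 pi I0(1)), I0 from its power series
        expected = np.e / (2 * np.pi * bessel_i0_series(1.0))
        assert von_mises_density(33.0, 33.0, 1.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("d", [1.0, 17.5, 45.0, 89.0])
    def test_even_symmetry_about_mean(self, d):
        mu = 73.0
        assert von_mises_density(mu + d, mu, 2.3) == pytest.approx(
            von_mises_density(mu - d, mu, 2.3), rel=1e-12)

    def test_periodic_in_x_and_mu(self):
        assert von_mises_density(12.0, 40.0, 1.5) == pytest.approx(
            von_mises_density(12.0 + 180.0, 40.0, 1.5), rel=1e-12)
        assert von_mises_density(12.0, 40.0, 1.5) == pytest.approx(
            von_mises_density(12.0, 40.0 - 180.0, 1.5), rel=1e-12)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            von_mises_density(0.0, 0.0, -0.5)

    def test_matches_independent_reference_on_grid(self):
        for x in (-30.0, 0.0, 20.0, 95.0):
            for kappa in (0.47, 1.12):
                assert von_mises_density(x, 20.0, kappa) == pytest.approx(
                    von_mises_ref(x, 20.0, kappa), rel=1e-12)


class TestLgnDrive:
    def test_zero_contrast_gives_zero(self, printed_params):
        theta = np.linspace(0, 180, 13)
        assert np.all(lgn_drive(theta, 20.0, 0.0, printed_params) == 0.0)

    def test_maximal_at_stimulus_orientation(self, printed_params):
        theta = printed_params.preferred_orientations
        drive = lgn_drive(theta, 20.0, 1.0, printed_params)
        # 20 deg falls between grid points; the peak is the nearest unit
        assert abs(theta[np.argmax(drive)] - 20.0) <= printed_params.unit_spacing / 2

    def test_peak_amplitude_matches_series_oracle(self, printed_params):
        expected = 11.04 / (2 * np.pi * bessel_i0_series(0.47)) * np.e**0.47
        assert lgn_drive(20.0, 20.0, 1.0, printed_params) == pytest.approx(
            expected, rel=1e-10)

    def test_proportional_to_contrast(self, printed_params):
        d1 = lgn_drive(5.0, 20.0, 1.0, printed_params)
        assert lgn_drive(5.0, 20.0, 0.35, printed_params) == pytest.approx(
            0.35 * d1, rel=1e-12)

    def test_negative_contrast_rejected(self, printed_params):
        with pytest.raises(ValueError):
            lgn_drive(0.0, 0.0, -0.1, printed_params)


class TestConnectionProfile:
    def test_even_in_orientation_difference(self, printed_params):
        d = np.array([3.0, 20.0, 45.0, 80.0])
        assert np.allclose(connection_profile(printed_params, d),
                           connection_profile(printed_params, -d))

    def test_mexican_hat_shape(self, printed_params):
        # With kappa_E > kappa_I the profile is maximal at 0 and minimal
        # at 90 deg; reference values via the series Bessel oracle.
        f0 = 2.84 * (von_mises_ref(0, 0, 1.12) - 1.24 * von_mises_ref(0, 0, 0.56))
        f90 = 2.84 * (von_mises_ref(90, 0, 1.12) - 1.24 * von_mises_ref(90, 0, 0.56))
        d = np.linspace(0.0, 90.0, 91)
        prof = connection_profile(printed_params, d)
        assert prof[0] == pytest.approx(f0, rel=1e-10)
        assert prof[-1] == pytest.approx(f90, rel=1e-10)
        assert f0 > 0 > f90
        assert np.argmax(prof) == 0
        # monotone decrease through the excitatory center into the
        # inhibitory surround (the hat's minimum lies in the surround)
        assert np.all(np.diff(prof[:50]) < 0)
        assert np.min(prof) <= f90 < 0

    def test_no_inhibition_is_positive_everywhere(self, printed_params):
        p = replace(printed_params, r_ie=1e-12)  # inhibition removed
        d = np.linspace(0, 179, 180)
        assert np.all(connection_profile(p, d) > 0)


class TestSimulate:
    def test_uncoupled_network_matches_closed_form(self, small_params, solver):
        # With J_cortex -> 0 each unit is a first-order low-pass of its
        # constant drive: V(t) = V_lgn (1 - exp(-t / tau)).
        p = replace(small_params, j_cortex=1e-15)
        proto = StimulusProtocol((StimulusEpoch(20.0, 1.0, 50.0),))
        traj = simulate(proto, p, solver)
        from ringtae.network import lgn_drive as drive_fn
        v_inf = drive_fn(p.preferred_orientations, 20.0, 1.0, p)
        expected = v_inf[None, :] * (1 - np.exp(-traj.times[:, None] / p.tau))
        assert np.allclose(traj.voltages, expected, atol=1e-6)
        assert np.allclose(traj.rates, p.alpha * np.maximum(traj.voltages, 0.0))

    def test_zero_contrast_stays_at_rest(self, small_params, solver):
        proto = StimulusProtocol((StimulusEpoch(20.0, 0.0, 30.0),
                                  StimulusEpoch(50.0, 0.0, 30.0)))
        traj = simulate(proto, small_params, solver)
        assert np.all(traj.rates == 0.0)

    def test_matches_forward_euler_oracle_two_epochs(self, small_params, solver):
        # The fixed-step Euler oracle converges at first order TOWARD the
        # adaptive solution: its distance halves when its step halves, and
        # at dt = 0.005 ms the two integrators agree to < 1e-3 Hz per unit.
        proto = StimulusProtocol((StimulusEpoch(20.0, 1.0, 25.0),
                                  StimulusEpoch(0.0, 1.0, 25.0)))
        traj = simulate(proto, small_params, solver)
        times, rates_coarse = euler_simulate(proto, small_params, dt=0.01)
        _, rates_fine = euler_simulate(proto, small_params, dt=0.005)
        assert np.allclose(traj.times, times)
        err_coarse = np.max(np.abs(traj.rates - rates_coarse))
        err_fine = np.max(np.abs(traj.rates - rates_fine))
        assert err_fine < 1e-3
        assert err_fine < err_coarse
        assert err_coarse / err_fine == pytest.approx(2.0, rel=0.15)

    def test_rotational_equivariance(self, small_params, solver):
        proto = StimulusProtocol.adapt_test(20.0, adapter_ms=30, test_ms=30)
        k = 4  # integer multiple of the unit spacing
        delta = k * small_params.unit_spacing
        traj = simulate(proto, small_params, solver)
        traj_rot = simulate(proto.rotated(delta), small_params, solver)
        assert np.allclose(traj_rot.rates, np.roll(traj.rates, k, axis=1),
                           atol=1e-6)

    def test_reflection_symmetry(self, small_params, solver):
        # Negating all stimulus orientations reflects the pattern about 0.
        proto = StimulusProtocol((StimulusEpoch(20.0, 1.0, 30.0),
                                  StimulusEpoch(40.0, 1.0, 20.0)))
        refl = StimulusProtocol((StimulusEpoch(-20.0, 1.0, 30.0),
                                 StimulusEpoch(-40.0, 1.0, 20.0)))
        traj = simulate(proto, small_params, solver)
        traj_r = simulate(refl, small_params, solver)
        # unit 0 maps to itself, unit i to n - i
        idx = (-np.arange(small_params.n_units)) % small_params.n_units
        assert np.allclose(traj_r.rates, traj.rates[:, idx], atol=1e-6)

    def test_steady_state_decodes_to_stimulus(self, printed_params, solver):
        proto = StimulusProtocol((StimulusEpoch(67.0, 1.0, 400.0),))
        traj = simulate(proto, printed_params, solver)
        decoded = decode_orientation(traj.final_rates, traj.preferred)
        assert abs(decoded - 67.0) < printed_params.unit_spacing / 2

    def test_output_grid_is_regular_and_spans_protocol(self, small_params, solver):
        proto = StimulusProtocol.adapt_test(10.0, adapter_ms=20, test_ms=35)
        traj = simulate(proto, small_params, solver)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(55.0)
        assert np.allclose(np.diff(traj.times), solver.dt_out)

    def test_trajectory_serializes_to_long_table(self, small_params, solver, tmp_path):
        proto = StimulusProtocol((StimulusEpoch(0.0, 1.0, 5.0),))
        traj = simulate(proto, small_params, solver)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_ms", "preferred_deg", "rate_hz"]
        assert len(df) == len(traj.times) * small_params.n_units


class TestConfig:
    def test_default_config_reproduces_fitted_set(self):
        from ringtae.config import default_config
        cfg = default_config()
        assert cfg["network"] == NetworkParams()
        assert cfg["solver"] == SolverSettings()
        assert cfg["protocol"].total_duration == 700.0

    def test_roundtrip_from_file(self, tmp_path):
        from ringtae.config import load_config
        path = tmp_path / "net.yaml"
        path.write_text(
            "network: {tau: 5.0, n_units: 64}\n"
            "solver: {dt_out: 0.5}\n"
            "protocol:\n  epochs:\n   - {orientation: 10, duration: 30}\n")
        cfg = load_config(path)
        assert cfg["network"].tau == 5.0
        assert cfg["network"].n_units == 64
        assert cfg["solver"].dt_out == 0.5
        assert cfg["protocol"].epochs[0].orientation == 10.0
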