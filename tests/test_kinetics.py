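"""Cross-catalytic growth model: closed form, fits, serial transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hairpinrep as hr
from hairpinrep import kinetics as kin, synth
from hairpinrep.kinetics import (
    CrossCatalyticModel,
    FitError,
    KineticsError,
    SerialTransferSpec,
    Trajectory,
)


class TestClosedForm:
    def test_no_dynamics_without_rates(self):
        c, cb = kin.closed_form(CrossCatalyticModel(0, 0), 7.0, 3.0, np.arange(5))
        assert np.allclose(c, 7.0) and np.allclose(cb, 3.0)

    def test_symmetric_start_stays_symmetric(self):
        c, cb = kin.closed_form(hr.REFERENCE_MODEL, 10.0, 10.0, np.linspace(0, 6, 13))
        assert np.allclose(c, cb)

    @given(
        k=st.floats(0.0, 1.0),
        k0=st.floats(0.0, 2.0),
        c0=st.floats(0.0, 50.0),
        cb0=st.floats(0.0, 50.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_numerical_integration(self, k, k0, c0, cb0):
        t = np.linspace(0, 6, 7)
        model = CrossCatalyticModel(k, k0)
        c, cb = kin.closed_form(model, c0, cb0, t)
        cn, cbn = kin.integrate_numerical(model, c0, cb0, t)
        scale = max(c.max(), 1.0)
        assert np.allclose(c, cn, rtol=1e-6, atol=1e-6 * scale)
        assert np.allclose(cb, cbn, rtol=1e-6, atol=1e-6 * scale)

    def test_difference_decays_at_rate_k(self):
        t = np.linspace(0, 6, 25)
        c, cb = kin.closed_form(hr.REFERENCE_MODEL, 20.0, 5.0, t)
        d = c - cb
        assert np.allclose(d, 15.0 * np.exp(-hr.REFERENCE_MODEL.k * t))
        assert np.all(np.diff(np.abs(d)) <= 1e-12)

    def test_zero_start_zero_spontaneous_stays_zero(self):
        c, cb = kin.closed_form(CrossCatalyticModel(0.3, 0.0), 0.0, 0.0, np.arange(10))
        assert np.all(c == 0) and np.all(cb == 0)

    def test_per_cycle_growth_factor_is_exp_k(self):
        """With c = c̄ and no spontaneous channel: pure exponential growth."""
        model = CrossCatalyticModel(0.16, 0.0)
        c, cb = kin.closed_form(model, 10.0, 10.0, np.arange(7))
        ratios = c[1:] / c[:-1]
        assert np.allclose(ratios, np.exp(model.k))

    def test_negative_input_rejected(self):
        with pytest.raises(KineticsError):
            kin.closed_form(hr.REFERENCE_MODEL, -1.0, 0.0, [0, 1])


class TestInitialVelocity:
    def test_no_template_limit_is_k0(self):
        assert kin.initial_velocity(hr.REFERENCE_MODEL, 0.0) == pytest.approx(0.4)

    def test_hand_value_and_finite_difference(self):
        model = CrossCatalyticModel(0.16, 0.4)
        v = kin.initial_velocity(model, 30.0)
        assert v == pytest.approx(5.2)
        eps = 1e-6
        c_eps, _ = kin.closed_form(model, 0.0, 30.0, np.array([eps]))
        assert c_eps[0] / eps == pytest.approx(v, rel=1e-4)

    def test_affine_in_template_with_slope_k(self):
        v = [kin.initial_velocity(hr.REFERENCE_MODEL, cb) for cb in (0, 10, 20, 40)]
        slopes = np.diff(v) / np.diff([0, 10, 20, 40])
        assert np.allclose(slopes, hr.REFERENCE_MODEL.k)


class TestCrossCatalyticFit:
    @given(k=st.floats(0.01, 0.8), k0=st.floats(0.01, 2.0))
    @settings(max_examples=15, deadline=None)
    def test_noiseless_recovery_is_exact(self, k, k0):
        model = CrossCatalyticModel(k, k0)
        t = np.arange(7, dtype=float)
        traces = [
            Trajectory(t, kin.closed_form(model, 0.0, cb0, t)[0], c_bar0=cb0)
            for cb0 in (0.0, 15.0, 45.0)
        ]
        fit = kin.fit_cross_catalytic(traces, n_boot=0)
        assert fit.model.k == pytest.approx(k, rel=1e-4, abs=1e-6)
        assert fit.model.k0 == pytest.approx(k0, rel=1e-4, abs=1e-6)

    def test_noisy_recovery_within_stated_bands(self):
        noise = synth.NoiseSpec(sigma_rel=0.10, sigma_abs=1.0, seed=5)
        df = synth.gen_amplification_traces(hr.REFERENCE_MODEL, replicates=20, noise=noise)
        fit = kin.fit_cross_catalytic(
            kin.frame_to_traces(df), total_per_strand=200.0, n_boot=0
        )
        assert fit.model.k == pytest.approx(0.16, rel=0.10)
        assert fit.model.k0 == pytest.approx(0.4, rel=0.25)

    def test_saturated_points_are_excluded(self):
        t = np.arange(7, dtype=float)
        c, _ = kin.closed_form(hr.REFERENCE_MODEL, 0.0, 30.0, t)
        c_sat = np.minimum(c, 30.0)  # clip to mimic saturation
        fit = kin.fit_cross_catalytic(
            [Trajectory(t, c_sat, c_bar0=30.0),
             Trajectory(t, kin.closed_form(hr.REFERENCE_MODEL, 0, 5.0, t)[0], c_bar0=5.0)],
            total_per_strand=40.0, saturation_fraction=0.5, n_boot=0,
        )
        assert fit.model.k == pytest.approx(0.16, rel=1e-3)

    def test_template_free_trace_reports_wide_k_interval(self):
        """k is weakly identified without template; the bootstrap interval
        must be honest about it rather than failing silently."""
        t = np.arange(7, dtype=float)
        c, _ = kin.closed_form(hr.REFERENCE_MODEL, 0.0, 0.0, t)
        rng = np.random.default_rng(2)
        noisy = c * (1 + 0.1 * rng.standard_normal(c.shape))
        fit = kin.fit_cross_catalytic(
            [Trajectory(t, noisy, c_bar0=0.0)], n_boot=30, seed=2
        )
        assert np.isfinite(fit.model.k0)
        width = fit.k_ci[1] - fit.k_ci[0]
        assert width > 0.05 or not np.isfinite(width)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            kin.fit_cross_catalytic(
                [Trajectory(np.array([0.0]), np.array([1.0]), c_bar0=1.0)], n_boot=0
            )


class TestSerialTransfer:
    def test_no_dilution_matches_closed_form(self):
        spec = SerialTransferSpec(cycles_per_transfer=3, dilution=1.0, n_transfers=3)
        traj = kin.simulate_serial_transfer(hr.REFERENCE_MODEL, spec, 30.0)
        c_ref, _ = kin.closed_form(hr.REFERENCE_MODEL, 0.0, 30.0, traj.t)
        assert np.allclose(traj.c, c_ref)

    def test_no_monomer_control_decays_geometrically(self):
        spec = SerialTransferSpec(3, 0.5, n_transfers=6, monomer_replenished=False)
        traj = kin.simulate_serial_transfer(hr.REFERENCE_MODEL, spec, 30.0)
        assert traj.final_state[1] == pytest.approx(30.0 * 0.5 ** 6)
        assert np.all(np.diff(traj.c_bar) <= 1e-12)

    def test_growth_balance_fixed_point(self):
        """When 3-cycle growth exactly cancels the dilution, the sampled
        trace at transfer boundaries is level."""
        spec = SerialTransferSpec(3, 0.5, n_transfers=5)
        k = np.log(2.0) / 3.0  # e^{3k} = 2 = 1/dilution
        model = CrossCatalyticModel(k, 0.0)
        traj = kin.simulate_serial_transfer(model, spec, 30.0, c0=30.0)
        boundary = traj.c[np.isin(traj.t, [3.0, 6.0, 9.0, 12.0, 15.0])]
        assert np.allclose(boundary, boundary[0])

    def test_dilution_fit_self_consistency(self):
        spec = SerialTransferSpec(3, 0.43, n_transfers=8)
        traj = kin.simulate_serial_transfer(hr.REFERENCE_MODEL, spec, 30.0)
        est = kin.fit_dilution_factor(traj, hr.REFERENCE_MODEL, spec)
        assert est == pytest.approx(0.43, abs=1e-3)

    def test_dilution_recovery_with_noise(self):
        noise = synth.NoiseSpec(sigma_rel=0.10, sigma_abs=1.0, seed=3)
        spec = SerialTransferSpec(3, 0.43, n_transfers=8)
        df = synth.gen_serial_transfer_trace(
            hr.REFERENCE_MODEL, spec, 30.0, noise, include_control=False
        )
        est = kin.fit_dilution_factor(
            kin.frame_to_traces(df)[0], hr.REFERENCE_MODEL, spec
        )
        assert est == pytest.approx(0.43, abs=0.05)

    def test_dilution_values_distinguishable(self):
        """0.43 and 0.50 generators stay separated at 10% noise."""
        ests = {}
        for dil, seed in ((0.43, 21), (0.50, 22)):
            spec = SerialTransferSpec(3, dil, n_transfers=8)
            df = synth.gen_serial_transfer_trace(
                hr.REFERENCE_MODEL, spec, 30.0,
                synth.NoiseSpec(0.10, 1.0, seed), include_control=False,
            )
            ests[dil] = kin.fit_dilution_factor(
                kin.frame_to_traces(df)[0], hr.REFERENCE_MODEL, spec
            )
        assert abs(ests[0.43] - 0.43) < abs(ests[0.43] - 0.50)
        assert abs(ests[0.50] - 0.50) < abs(ests[0.50] - 0.43)


class TestSigmoidFit:
    def test_flat_series_flagged_with_zero_amplitude(self):
        t = np.linspace(0, 10, 20)
        fit = kin.fit_sigmoid(t, np.full_like(t, 2.0))
        assert fit.flat and fit.amplitude == 0.0

    def test_noiseless_logistic_recovered(self):
        t = np.linspace(0, 20, 50)
        y = 3.0 * (1 + 4.0 / (1 + np.exp(-0.9 * (t - 8.0))))
        fit = kin.fit_sigmoid(t, y)
        assert fit.amplitude == pytest.approx(4.0, rel=0.02)
        assert fit.midpoint == pytest.approx(8.0, abs=0.2)

    def test_noisy_amplitude_within_5_percent(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 20, 60)
        y = 1 + 5.0 / (1 + np.exp(-0.7 * (t - 9.0)))
        y = y * (1 + 0.05 * rng.standard_normal(t.shape))
        fit = kin.fit_sigmoid(t, y)
        assert fit.amplitude == pytest.approx(5.0, rel=0.05)


class TestTraceIO:
    def test_tsv_round_trip(self, tmp_path):
        noise = synth.NoiseSpec(seed=4)
        df = synth.gen_amplification_traces(hr.REFERENCE_MODEL, replicates=2, noise=noise)
        traces = kin.frame_to_traces(df)
        path = tmp_path / "traces.tsv"
        kin.write_traces(traces, path)
        back = kin.read_traces(path)
        assert len(back) == len(traces)
        for a, b in zip(traces, back):
            assert np.allclose(a.c, b.c) and a.c_bar0 == b.c_bar0
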