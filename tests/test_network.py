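"""Plasticity network: elementary ops, conservation, calibration, protocols."""

import dataclasses

import numpy as np
import pytest

import driftsteer as ds
from driftsteer import network as nw
from driftsteer.errors import (
    CalibrationError,
    DeadNeuronError,
    NumericalFailureError,
    ParameterError,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n", 1), ("epsilon", -1.0), ("epsilon", 0.0), ("k", 1.5), ("k", -0.1),
        ("stimuli_per_day", 0), ("noise_sd", -0.5), ("presyn_width", 0.0),
        ("warmup_days", -1), ("grid_step", 0.0),
    ])
    def test_invalid_field_named(self, field, value):
        with pytest.raises(ParameterError) as err:
            nw.ModelConfig(**{field: value})
        assert field in str(err.value)

    def test_protocol_validation(self):
        with pytest.raises(ParameterError):
            nw.Phase("twilight", 5)
        with pytest.raises(ParameterError):
            nw.Phase("deprivation", 5)  # theta_hat missing
        with pytest.raises(ParameterError):
            nw.Phase("baseline", 0)
        with pytest.raises(ParameterError):
            nw.ProtocolSpec(phases=())

    def test_stimuli_per_day_is_twelve_waking_hours_at_one_hz(self):
        assert nw.ModelConfig().stimuli_per_day == 60 * 60 * 12 == 43_200


class TestPresynResponse:
    def test_peak_at_center_and_symmetry(self):
        cfg = nw.ModelConfig(n=100)
        centers = nw._centers(100)
        u = nw.presyn_response(centers[30], cfg)
        assert np.argmax(u) == 30
        assert u[30] == pytest.approx(cfg.presyn_offset + cfg.presyn_amplitude)
        u_plus = nw.presyn_response(centers[30] + 7.0, cfg)
        u_minus = nw.presyn_response(centers[30] - 7.0, cfg)
        assert u_plus[30] == pytest.approx(u_minus[30])

    def test_population_drive_is_translation_invariant(self):
        cfg = nw.ModelConfig(n=500)
        totals = [nw.presyn_response(th, cfg).sum() for th in (-90.0, -33.3, 0.0, 17.7, 61.0)]
        assert np.ptp(totals) / np.mean(totals) < 0.01


class TestForward:
    def test_zero_and_single_weight(self):
        cfg = nw.ModelConfig(n=4)
        state = nw.init_network(cfg)
        state.w[:] = 0.0
        u = np.arange(4.0)
        assert np.allclose(nw.forward(state, u), 0.0)
        state.w[2, 1] = 1.0
        v = nw.forward(state, u)
        assert v[1] == pytest.approx(u[2])

    def test_matches_double_loop_oracle(self, rng):
        cfg = nw.ModelConfig(n=6)
        state = nw.init_network(cfg)
        state.w[:] = rng.random((6, 6)) * 0.1
        u = rng.random(6)
        v = nw.forward(state, u)
        for i in range(6):
            assert v[i] == pytest.approx(sum(state.w[j, i] * u[j] for j in range(6)))


class _FixedNoise:
    """Stub rng whose 'standard normal' draws are a constant."""

    def __init__(self, value):
        self.value = value

    def standard_normal(self, shape, dtype=np.float64):
        return np.full(shape, self.value, dtype=dtype)


class TestPlasticityStep:
    def test_zero_weights_are_frozen(self):
        cfg = nw.ModelConfig(n=5, noise_sd=2.0)
        state = nw.init_network(cfg)
        state.w[:] = 0.0
        nw.plasticity_step(state, 10.0, cfg)
        assert np.all(state.w == 0.0)  # rho(0) = 0 gates all plasticity

    def test_no_hebbian_no_noise_no_change(self):
        cfg = nw.ModelConfig(n=5, k=0.0, noise_sd=0.0)
        state = nw.init_network(cfg)
        before = state.w.copy()
        nw.plasticity_step(state, 0.0, cfg)
        assert np.array_equal(state.w, before)

    def test_scalar_oracle_single_synapse(self, monkeypatch):
        # target synapse: w=0.5, u_j=2, v_i=3, k=1, xi=0.1, eps=1e-4
        # -> dw = 1e-4 * tanh(5) * (2*3 + 0.1), evaluated by hand
        cfg = nw.ModelConfig(n=2, epsilon=1e-4, k=1.0, noise_sd=1.0)
        state = nw.init_network(cfg)
        state.rng = _FixedNoise(0.1)
        state.w[:] = 0.0
        state.w[0, 1] = 0.5
        state.w[1, 1] = 0.5
        u = np.array([2.0, 4.0])  # v[1] = 0.5*2 + 0.5*4 = 3
        monkeypatch.setattr(nw, "presyn_response", lambda theta, config, centers=None: u)
        expected = 0.5 + 1e-4 * np.tanh(10 * 0.5) * (2.0 * 3.0 + 0.1)
        nw.plasticity_step(state, 0.0, cfg)
        assert state.w[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_nonfinite_weight_raises(self):
        cfg = nw.ModelConfig(n=3, noise_sd=0.0)
        state = nw.init_network(cfg)
        state.w[0, 0] = np.inf
        with pytest.raises(NumericalFailureError):
            nw.plasticity_step(state, 0.0, cfg)

    def test_day_loop_bit_identical_to_step_loop(self):
        cfg = nw.ModelConfig(n=8, stimuli_per_day=25, epsilon=1e-3)
        thetas = np.random.default_rng(3).uniform(-90, 90, 25)
        s1 = nw.init_network(cfg, np.random.default_rng(9))
        for th in thetas:
            nw.plasticity_step(s1, th, cfg)
        s2 = nw.init_network(cfg, np.random.default_rng(9))
        bh = np.empty((8, 8)); bz = np.empty((8, 8), np.float32); br = np.empty((8, 8))
        nw._run_day(s2.w, thetas, s2.presyn_centers, cfg, s2.rng, bh, bz, br)
        assert np.array_equal(s1.w, s2.w)


class TestNormalization:
    def test_sums_become_exactly_one(self, rng):
        cfg = nw.ModelConfig(n=50)
        state = nw.init_network(cfg)
        state.w[:] = rng.random((50, 50)) + 0.01
        nw.normalize_incoming(state)
        assert np.abs(state.incoming_sums() - 1.0).max() < 1e-12

    def test_idempotent(self, rng):
        cfg = nw.ModelConfig(n=20)
        state = nw.init_network(cfg)
        state.w[:] = rng.random((20, 20)) + 0.01
        nw.normalize_incoming(state)
        w1 = state.w.copy()
        nw.normalize_incoming(state)
        assert np.allclose(state.w, w1, rtol=0, atol=1e-15)

    def test_single_synapse_becomes_one(self):
        cfg = nw.ModelConfig(n=4)
        state = nw.init_network(cfg)
        state.w[:] = 0.0
        state.w[np.arange(4), np.arange(4)] = 0.3
        nw.normalize_incoming(state)
        assert np.allclose(state.w[np.arange(4), np.arange(4)], 1.0)

    def test_dead_neuron_identified(self):
        cfg = nw.ModelConfig(n=4)
        state = nw.init_network(cfg)
        state.w[:, 2] = 0.0
        with pytest.raises(DeadNeuronError) as err:
            nw.normalize_incoming(state)
        assert "2" in str(err.value)


class TestInitAndMeasure:
    def test_init_sums_one_and_width_sd_zero_uniform(self):
        cfg = nw.ModelConfig(n=64, width_log_sd=0.0)
        state = nw.init_network(cfg)
        assert np.abs(state.incoming_sums() - 1.0).max() < 1e-12
        assert np.allclose(state.widths, state.widths[0])

    def test_fresh_network_pos_equal_assigned_centers(self):
        cfg = nw.ModelConfig(n=80)
        state = nw.init_network(cfg)
        pos = nw.measure_pos(state, cfg)
        assert np.allclose(ds.orientation_distance(pos, state.assigned_po), 0.0,
                           atol=cfg.effective_grid_step)

    def test_measurement_is_frozen_and_repeatable(self):
        cfg = nw.ModelConfig(n=40)
        state = nw.init_network(cfg)
        w_before = state.w.copy()
        p1 = nw.measure_pos(state, cfg)
        p2 = nw.measure_pos(state, cfg)
        assert np.array_equal(p1, p2)
        assert np.array_equal(state.w, w_before)

    def test_tie_breaks_to_smaller_angle(self):
        cfg = nw.ModelConfig(n=10, presyn_width=5.0, presyn_offset=0.0)
        state = nw.init_network(cfg)
        state.w[:] = 0.0
        state.w[2, 0] = 0.5   # two equal peaks for neuron 0
        state.w[7, 0] = 0.5
        pos = nw.measure_pos(state, cfg)
        assert pos[0] == pytest.approx(state.presyn_centers[2], abs=cfg.effective_grid_step)


class TestCalibration:
    def test_doubling_noise_doubles_hebbian_gain(self):
        cfg1 = nw.ModelConfig(n=60, noise_sd=1.0)
        cfg2 = nw.ModelConfig(n=60, noise_sd=2.0)
        c1 = nw.calibrate_hebbian_noise_parity(cfg1)
        c2 = nw.calibrate_hebbian_noise_parity(cfg2)
        assert c2.hebbian_gain / c1.hebbian_gain == pytest.approx(2.0, rel=1e-9)

    def test_per_step_mode_reaches_exact_parity(self):
        cfg = nw.ModelConfig(n=60)
        cal = nw.calibrate_hebbian_noise_parity(cfg, mode="per_step_abs")
        assert 0.95 <= cal.achieved_ratio <= 1.05
        # re-measure mean |H| with the calibrated rates against mean |xi|
        cfg2 = dataclasses.replace(cfg, presyn_amplitude=cal.presyn_amplitude,
                                   presyn_offset=cal.presyn_offset)
        state = nw.init_network(cfg2, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        hs = []
        for th in rng.uniform(-90, 90, 64):
            u = nw.presyn_response(th, cfg2, state.presyn_centers)
            hs.append(np.abs(np.outer(u, state.w.T @ u)).mean())
        ratio = np.mean(hs) / (cfg.noise_sd * np.sqrt(2 / np.pi))
        assert 0.9 <= ratio <= 1.1

    def test_zero_noise_rejected(self):
        with pytest.raises(CalibrationError):
            nw.calibrate_hebbian_noise_parity(nw.ModelConfig(n=30, noise_sd=0.0))

    def test_deterministic_given_seed(self):
        cfg = nw.ModelConfig(n=40, seed=5)
        a = nw.calibrate_hebbian_noise_parity(cfg)
        b = nw.calibrate_hebbian_noise_parity(cfg)
        assert a == b

    def test_per_day_target_invariant_under_rescale(self):
        cfg = nw.ModelConfig(n=40)
        a = nw.calibrate_hebbian_noise_parity(cfg)
        b = nw.calibrate_hebbian_noise_parity(nw.rescale_for_desk(cfg, 100))
        assert a.presyn_amplitude == pytest.approx(b.presyn_amplitude, rel=1e-12)


class TestRescale:
    def test_identity_at_one(self):
        cfg = nw.ModelConfig()
        assert nw.rescale_for_desk(cfg, 1) is cfg

    def test_preserves_daily_hebbian_and_noise_scales(self):
        cfg = nw.ModelConfig()
        d = nw.rescale_for_desk(cfg, 100)
        assert d.epsilon * d.stimuli_per_day == pytest.approx(cfg.epsilon * cfg.stimuli_per_day)
        assert (d.epsilon * d.noise_sd * np.sqrt(d.stimuli_per_day)
                == pytest.approx(cfg.epsilon * cfg.noise_sd * np.sqrt(cfg.stimuli_per_day)))

    def test_non_divisor_rejected(self):
        with pytest.raises(ParameterError):
            nw.rescale_for_desk(nw.ModelConfig(), 7)  # 7 does not divide 43200

    def test_scaled_runs_statistically_consistent(self):
        """Median baseline drift agrees between two desk-scale factors."""
        base = nw.calibrated_config(nw.ModelConfig(n=60, warmup_days=1))
        mags = {}
        for c in (1200, 2400):
            d = nw.rescale_for_desk(base, c)
            m = [np.median(nw.run_protocol(d, nw.baseline_protocol(6, measure_every=6),
                                           seed=100 + s).drift_magnitude(0, 6))
                 for s in range(6)]
            mags[c] = np.mean(m)
        assert mags[1200] == pytest.approx(mags[2400], rel=0.5)
        assert mags[1200] > 0.1  # the comparison is not vacuous


class TestProtocols:
    def test_fully_ablated_network_is_static(self, tiny_model_config):
        cfg = dataclasses.replace(tiny_model_config, k=0.0, noise_sd=0.0)
        traj = nw.run_protocol(cfg, nw.baseline_protocol(3), seed=1)
        assert np.allclose(traj.po[0], traj.po[-1])
        assert traj.max_norm_deviation < 1e-12

    def test_same_seed_reproduces_trajectory(self, tiny_model_config):
        p = nw.deprivation_protocol(3, theta_hat=10.0)
        t1 = nw.run_protocol(tiny_model_config, p, seed=7)
        t2 = nw.run_protocol(tiny_model_config, p, seed=7)
        assert np.array_equal(t1.po, t2.po)
        t3 = nw.run_protocol(tiny_model_config, p, seed=8)
        assert not np.array_equal(t1.po, t3.po)

    def test_conservation_after_every_day(self, tiny_model_config):
        traj = nw.run_protocol(tiny_model_config, nw.baseline_protocol(4), seed=2)
        assert traj.max_norm_deviation < 1e-12

    def test_hebbian_only_deprivation_collapses_to_target(self):
        """With volatility off and a strong Hebbian term, a long single-
        orientation diet pulls every PO onto the experienced orientation."""
        cfg = nw.ModelConfig(n=48, stimuli_per_day=150, epsilon=2e-3, noise_sd=0.0,
                             presyn_amplitude=1.0, presyn_offset=0.1, warmup_days=0)
        traj = nw.run_protocol(cfg, nw.deprivation_protocol(30, theta_hat=-25.0,
                                                            measure_every=30), seed=3)
        final_rpo = ds.orientation_distance(traj.po[-1], -25.0)
        assert np.median(final_rpo) < 2 * cfg.effective_grid_step

    def test_measurement_days_and_conditions(self, tiny_model_config):
        p = nw.ProtocolSpec(phases=(nw.Phase("baseline", 2),
                                    nw.Phase("deprivation", 2, theta_hat=0.0)),
                            measure_every=2)
        traj = nw.run_protocol(tiny_model_config, p, seed=1)
        assert traj.days.tolist() == [0, 2, 4]
        assert traj.condition_by_day == ["start", "baseline", "deprivation"]

    def test_recovery_is_slow_and_incomplete(self):
        """After deprivation, an equal-length baseline diet drifts POs back
        outward, but the distribution stays biased toward the experienced
        orientation."""
        cfg = nw.rescale_for_desk(nw.calibrated_config(nw.ModelConfig(n=100)), 600)
        proto = nw.recovery_protocol(14, 14, theta_hat=0.0, measure_every=14)
        resid, dep_conv, rec_conv = [], [], []
        for s in range(4):
            t = nw.run_protocol(cfg, proto, seed=40 + s)
            rpo = ds.orientation_distance(t.po, 0.0)
            dep_conv.append(np.median(rpo[0] - rpo[1]))   # during deprivation
            rec_conv.append(np.median(rpo[1] - rpo[2]))   # during recovery
            resid.append(np.median(rpo[0]) - np.median(rpo[2]))
        assert np.mean(dep_conv) > 0.5
        assert np.mean(rec_conv) < 0.0            # population drifts back out
        assert abs(np.mean(rec_conv)) < np.mean(dep_conv)
        assert np.mean(resid) > 0.0               # ...but not all the way back

    def test_baseline_drift_rate_is_stationary(self):
        """Day-to-day drift rate shows no trend across baseline days."""
        cfg = nw.rescale_for_desk(nw.calibrated_config(nw.ModelConfig(n=100)), 600)
        slopes = []
        for s in range(4):
            t = nw.run_protocol(cfg, nw.baseline_protocol(12), seed=60 + s)
            series = t.drift_rate_series()
            slopes.append(np.polyfit(series.day, series.mean_rate, 1)[0])
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < max(3 * se, 0.01)

    def test_interrupted_deprivation_slows_convergence(self):
        cfg = nw.ModelConfig(n=48, stimuli_per_day=160, epsilon=1e-3, noise_sd=0.0,
                             presyn_amplitude=0.6, presyn_offset=0.06, warmup_days=0)
        dep = nw.run_protocol(cfg, nw.deprivation_protocol(14, theta_hat=0.0,
                                                           measure_every=14), seed=4)
        intr = nw.run_protocol(cfg, nw.interrupted_deprivation_protocol(
            14, theta_hat=0.0, period_days=3, exposure_fraction=0.5,
            measure_every=14), seed=4)
        conv_dep = np.median(dep.convergence(0.0, 0, 14))
        conv_intr = np.median(intr.convergence(0.0, 0, 14))
        assert conv_intr < conv_dep


class TestDeprivationAnalysis:
    def test_degenerate_inputs_flagged(self, tiny_model_config):
        cfg = dataclasses.replace(tiny_model_config, k=0.0, noise_sd=0.0)
        traj = nw.run_protocol(cfg, nw.deprivation_protocol(2, theta_hat=0.0), seed=1)
        summ = nw.deprivation_analysis(traj, 0.0)
        assert summ.degenerate
        assert summ.spearman_r == 0.0

    def test_constructed_perfect_rank_correlation(self, tiny_model_config):
        traj = nw.run_protocol(tiny_model_config, nw.baseline_protocol(1), seed=1)
        # overwrite POs: drift magnitude exactly equals initial |rPO|
        n = traj.po.shape[1]
        rpo0 = np.linspace(5, 80, n)
        traj.po = np.stack([rpo0, np.zeros(n)])  # drifted all the way to 0
        traj.days = np.array([0, 1])
        summ = nw.deprivation_analysis(traj, 0.0)
        assert summ.spearman_r == pytest.approx(1.0)

    def test_records_feed_shuffle_machinery(self, tiny_model_config):
        traj = nw.run_protocol(tiny_model_config, nw.deprivation_protocol(
            2, theta_hat=15.0), seed=6)
        summ = nw.deprivation_analysis(traj, 15.0)
        res = ds.shuffle_test(summ.records, "direction", n_shuffle=50, rng=0)
        assert res.medians.shape == (50,)


class TestModelResultsFacade:
    def test_simulate_and_summary(self):
        model = nw.PlasticityModel(nw.ModelConfig(n=32, stimuli_per_day=60,
                                                  epsilon=5e-4, warmup_days=1))
        res = model.simulate(nw.baseline_protocol(2), seed=3, n_iter=2)
        assert res.n_iter == 2
        text = res.summary()
        assert "median drift rate" in text and "ensemble size" in text
        rates = res.median_drift_rates()
        assert rates.shape == (2,) and np.all(rates >= 0)

    def test_ablation_uses_precalibrated_config(self):
        base = nw.calibrated_config(nw.ModelConfig(n=32))
        ablated = dataclasses.replace(base, noise_sd=0.0)
        model = nw.PlasticityModel(ablated, calibrate=True)  # skips (noise off)
        assert model.config.presyn_amplitude == base.presyn_amplitude
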