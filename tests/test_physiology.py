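import numpy as np
import pytest

from cerloop import synth
from cerloop.physiology import (IPSCTrain, build_footprint, build_input_map,
                                convergence_estimate, detect_ipsc,
                                estimate_pool, fit_depression_train,
                                quantal_metrics, steady_state_analysis)


def _train(amps, freq=50.0, charges=None):
    n = len(amps)
    return IPSCTrain(frequency_hz=freq,
                     stimulus_times_ms=np.arange(n) * 1000.0 / freq,
                     amplitudes_pa=np.asarray(amps, dtype=float),
                     charges_pc=charges)


class TestDepressionFit:
    def test_constant_train_has_unit_plateau_and_no_tau(self):
        fit = fit_depression_train(_train(np.full(40, 80.0)))
        assert fit.plateau == pytest.approx(1.0)
        assert not fit.tau_identifiable

    def test_recovers_planted_exponential(self):
        tau_true = 10.0
        n = np.arange(60)
        amps = 100.0 * (0.5 + 0.5 * np.exp(-n / tau_true))
        fit = fit_depression_train(_train(amps))
        assert fit.tau_stimuli == pytest.approx(tau_true, rel=0.05)
        assert fit.plateau == pytest.approx(0.5, abs=0.02)

    def test_paper_matched_preset_halves_initial_strength(self):
        """Two-pool preset with activity-locked mobilization sustains
        steady-state IPSCs near half the initial amplitude."""
        train, truth = synth.gen_ipsc_trains(
            synth.paper_matched_ipsc_spec(frequency_hz=50.0, seed=3))
        fit = fit_depression_train(train)
        assert fit.plateau == pytest.approx(0.5, abs=0.1)


class TestSteadyState:
    def test_identical_plateaus_give_zero_slope(self):
        fits = [fit_depression_train(_train(np.full(40, 60.0)))
                for _ in range(3)]
        res = steady_state_analysis(fits, [10.0, 50.0, 100.0])
        assert res["plateau_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_charge_transfer_rises_with_frequency_at_fixed_plateau(self):
        fits = [fit_depression_train(_train(np.full(40, 60.0)))
                for _ in range(3)]
        res = steady_state_analysis(fits, [10.0, 50.0, 100.0])
        assert np.all(np.diff(res["charge_transfer"]) > 0)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            steady_state_analysis([], [])


class TestPoolEstimate:
    def test_zero_depression_train_slope_equals_charge(self):
        c = 2.0
        train = _train(np.full(60, 50.0), charges=np.full(60, c))
        est = estimate_pool(train)
        assert est.mobilization_pc_per_stim == pytest.approx(c, rel=1e-9)
        assert est.rrp_charge_pc == pytest.approx(0.0, abs=1e-6)

    def test_recovers_planted_rrp_of_100_quanta(self):
        errs = []
        for seed in range(20):
            train, truth = synth.gen_ipsc_trains(
                synth.rrp_recovery_ipsc_spec(seed=seed))
            est = estimate_pool(train, mean_quantal_charge_pc=0.10)
            errs.append(abs(est.rrp_quanta - 100.0) / 100.0)
        assert np.median(errs) < 0.10

    def test_mobilization_accelerates_with_frequency(self):
        per_s = {}
        for f in (20.0, 100.0):
            train, truth = synth.gen_ipsc_trains(
                synth.paper_matched_ipsc_spec(frequency_hz=f, seed=1))
            est = estimate_pool(train, mean_quantal_charge_pc=0.10)
            per_s[f] = est.mobilization_quanta_per_s
        assert per_s[100.0] > per_s[20.0]

    def test_short_trains_rejected(self):
        with pytest.raises(ValueError):
            estimate_pool(_train(np.full(30, 10.0), charges=np.full(30, 1.0)))


class TestQuantalMetrics:
    def test_release_probability_from_reported_quantities(self):
        out = quantal_metrics(evoked_amp_pa=56.1, spont_amp_pa=18.0,
                              holding_mv=-50.0, evoked_integral_qc=6.7,
                              rrp_quanta=99.0)
        assert out["release_probability"] == pytest.approx(0.0677, abs=0.001)

    def test_conductance_from_amplitude_and_driving_force(self):
        out = quantal_metrics(39.1, 18.0, holding_mv=-40.0, reversal_mv=-74.0)
        assert out["conductance_ns"] == pytest.approx(1.15, abs=0.005)
        assert quantal_metrics(0.0, 18.0, -40.0)["conductance_ns"] == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            quantal_metrics(10.0, 0.0, -40.0)
        with pytest.raises(ZeroDivisionError):
            quantal_metrics(10.0, 5.0, -74.0, reversal_mv=-74.0)


class TestDetectIpsc:
    def _event(self, amp, onset_ms, tau_rise=1.0, dt=0.05, length_ms=40.0):
        t = np.arange(0, length_ms, dt)
        x = np.where(t >= onset_ms,
                     amp * (1 - np.exp(-(t - onset_ms) / tau_rise)), 0.0)
        return x, t

    def test_subthreshold_event_not_detected(self):
        x, _ = self._event(10.0, 10.0)
        assert not detect_ipsc(x, flash_time_ms=0.0, dt_ms=0.05)["detected"]

    def test_event_outside_window_not_detected(self):
        x, _ = self._event(30.0, 28.0)
        res = detect_ipsc(x, flash_time_ms=0.0, dt_ms=0.05)
        assert not res["detected"]

    def test_onset_and_rise_time_recovered(self):
        """Exponential rise, tau 1 ms, amplitude 40 pA, onset 8 ms: the
        20-80% line extrapolation recovers onset within 0.3 ms and the
        rise time within 0.2 ms of the analytic value."""
        x, _ = self._event(40.0, 8.0, tau_rise=1.0)
        res = detect_ipsc(x, flash_time_ms=0.0, dt_ms=0.05)
        assert res["detected"]
        # analytic 20-80% interval for a saturating exponential whose peak
        # within the window is below the asymptote
        t_win_end = 24.0
        peak = 40.0 * (1 - np.exp(-(t_win_end - 8.0) / 1.0))
        t20 = -np.log(1 - 0.2 * peak / 40.0)
        t80 = -np.log(1 - 0.8 * peak / 40.0)
        assert res["rise_time_ms"] == pytest.approx(t80 - t20, abs=0.2)
        assert res["latency_ms"] == pytest.approx(8.0, abs=0.3)

    def test_no_event_inside_window_never_detected(self):
        x = np.zeros(1000)
        x[600:] = 50.0        # event at 30 ms with dt 0.05
        assert not detect_ipsc(x, 0.0, dt_ms=0.05)["detected"]


class TestMaps:
    def test_probability_rule_retains_two_of_three(self):
        maps = np.zeros((3, 32, 32))
        maps[0, 5, 5] = maps[1, 5, 5] = 40.0        # p = 2/3 at (5,5)
        maps[0, 5, 6] = maps[1, 5, 6] = maps[2, 5, 6] = 40.0
        maps[0, 20, 20] = 40.0                       # p = 1/3: dropped
        from cerloop.physiology import MapGrid
        field = build_input_map(MapGrid(maps))
        assert field.pixels[5, 5] and field.pixels[5, 6]
        assert not field.pixels[20, 20]

    def test_isolated_single_pixel_excluded(self):
        maps = np.zeros((2, 32, 32))
        maps[:, 10, 10] = 40.0                       # lone pixel, p = 1
        maps[:, 3:5, 3:5] = 40.0                     # 4-pixel cluster
        from cerloop.physiology import MapGrid
        field = build_input_map(MapGrid(maps))
        assert not field.pixels[10, 10]
        assert field.pixels[3:5, 3:5].all()
        assert field.area_um2 == pytest.approx(4 * 256.0)
        assert field.n_clusters == 1

    def test_planted_field_recovered_despite_spontaneous_noise(self):
        planted = np.zeros((32, 32), dtype=bool)
        planted[10:13, 10:13] = True
        hits = 0
        for seed in range(30):
            grid, _ = synth.gen_map_trials(planted, spontaneous_rate=0.02,
                                           n_repeats=3, seed=seed,
                                           response_probability=0.98)
            field = build_input_map(grid)
            hits += np.array_equal(field.pixels, planted)
        assert hits >= 27        # exact recovery in >= 90% of seeds

    def test_footprint_requires_all_repeats(self):
        maps = np.zeros((2, 32, 32))
        maps[:, 8:10, 8:10] = 1.0
        maps[0, 15, 15] = 1.0                        # 1/2 repeats: excluded
        from cerloop.physiology import MapGrid
        fp = build_footprint(MapGrid(maps, kind="spike"))
        assert fp.pixels[8:10, 8:10].all()
        assert not fp.pixels[15, 15]

    def test_convergence_ratio_and_clusters(self):
        planted = np.zeros((32, 32), dtype=bool)
        planted[4:7, 4:7] = True                     # field A: 9 px
        planted[20:23, 20:23] = True                 # field B: 9 px
        grid, _ = synth.gen_map_trials(planted, 0.0, 2, seed=0,
                                       response_probability=1.0)
        field = build_input_map(grid)
        assert field.n_clusters == 2
        res = convergence_estimate(field, [9 * 256.0])
        assert res["ratio"] == pytest.approx(2.0)
        res2 = convergence_estimate(field, [18 * 256.0])
        assert res2["ratio"] == pytest.approx(1.0)
        assert "one to two" in res2["interpretation"]

    def test_area_additivity_of_disjoint_clusters(self):
        planted = np.zeros((32, 32), dtype=bool)
        planted[2:4, 2:4] = True
        planted[28:31, 28:31] = True
        grid, _ = synth.gen_map_trials(planted, 0.0, 2, seed=0,
                                       response_probability=1.0)
        field = build_input_map(grid)
        assert field.area_um2 == pytest.approx((4 + 9) * 256.0)
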