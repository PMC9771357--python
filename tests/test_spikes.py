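import numpy as np
import pytest

from cerloop import synth
from cerloop.spikes import (InsufficientDataError, RateTrace, SpikeTrain,
                            causal_gaussian_kernel, classify_putative_pcmli,
                            cr_correlation, event_triggered_correlogram,
                            fit_two_gaussian_mixture, group_trials,
                            instantaneous_rate, normalize_rate,
                            pre_cr_fraction, select_extreme_isi_starts,
                            spike_triggered_correlogram)


class TestInstantaneousRate:
    def test_empty_train_gives_zero_rate(self):
        r = instantaneous_rate([], duration=500)
        assert np.all(r.rate == 0)

    def test_single_spike_peak_and_decay(self):
        """One-sided Gaussian, sigma 25 ms: peak 2/(sigma*sqrt(2*pi))
        ~ 31.9 Hz at the spike, times e^-0.5 one sigma later."""
        r = instantaneous_rate([100.0], duration=400, kernel_sd=25.0)
        assert np.all(r.rate[:100] == 0)             # nothing before the spike
        peak = r.rate[100]
        assert peak == pytest.approx(2000.0 / (25.0 * np.sqrt(2 * np.pi)),
                                     rel=0.02)
        assert r.rate[125] == pytest.approx(peak * np.exp(-0.5), rel=0.02)

    def test_rate_integral_equals_spike_count(self):
        r = instantaneous_rate([50.0, 300.0, 301.0], duration=2000)
        assert r.rate.sum() / 1000.0 == pytest.approx(3.0, rel=1e-6)

    def test_regular_train_matches_brute_force_convolution(self):
        spikes = np.arange(0, 1000, 10.0)            # 100 Hz for 1 s
        r = instantaneous_rate(spikes, duration=1200)
        # independent brute-force oracle: direct kernel summation
        k = causal_gaussian_kernel(25.0)
        t = np.arange(1200)
        brute = np.zeros(1200)
        for s in spikes:
            lag = t - int(s)
            ok = (lag >= 0) & (lag < len(k))
            brute[ok] += k[lag[ok]] * 1000.0
        assert np.allclose(r.rate, brute, atol=1e-9)
        # interior mean is the true rate (the causal kernel leaves ripple
        # at the stimulus period but no bias)
        assert r.rate[300:900].mean() == pytest.approx(100.0, abs=2.0)

    def test_causality_future_spikes_do_not_change_past(self):
        a = instantaneous_rate([100.0], duration=300)
        b = instantaneous_rate([100.0, 250.0], duration=300)
        assert np.array_equal(a.rate[:250], b.rate[:250])


class TestNormalization:
    def test_pc_flat_rate_normalizes_to_one(self):
        r = RateTrace(np.full(700, 60.0), t_start=-200.0)
        n = normalize_rate(r, "PC")
        assert np.allclose(n.rate, 1.0)
        assert n.normalization == "pc_baseline"

    def test_mli_normalized_by_session_cs_max(self):
        r = RateTrace(np.full(700, 20.0), t_start=-200.0)
        n = normalize_rate(r, "MLI", mli_session_cs_max_hz=40.0)
        assert np.allclose(n.rate, 0.5)

    def test_differently_modulated_mlis_contribute_equal_scales(self):
        """MLIs with 2x and 8x CS modulation both peak at 1 after
        normalization by their own session-average CS maximum."""
        t = np.arange(700) - 200.0
        bump = np.exp(-0.5 * ((t - 300) / 60.0) ** 2)
        for mod in (2.0, 8.0):
            rate = 10.0 * (1 + (mod - 1) * bump)
            r = RateTrace(rate, t_start=-200.0)
            mx = rate[(t >= 0)].max()
            n = normalize_rate(r, "MLI", mli_session_cs_max_hz=mx)
            assert n.rate.max() == pytest.approx(1.0)

    def test_zero_normalizer_raises(self):
        r = RateTrace(np.zeros(700), t_start=-200.0)
        with pytest.raises(ZeroDivisionError):
            normalize_rate(r, "PC", pc_baseline_hz=0.0)


class TestCrCorrelation:
    def test_proportional_traces_give_unit_correlation(self):
        t = np.arange(900) - 200.0
        sig = np.maximum(0, t - 250) * 0.01
        rate = RateTrace(5 * sig + 7, t_start=-200.0)
        res = cr_correlation([rate], [sig], [True], us_onset_ms=500.0)
        assert res.r_per_trial[0] == pytest.approx(1.0)
        res = cr_correlation([RateTrace(-5 * sig + 40, t_start=-200.0)],
                             [sig], [True], us_onset_ms=500.0)
        assert res.r_per_trial[0] == pytest.approx(-1.0)

    def test_zero_variance_trials_excluded(self):
        rate = RateTrace(np.full(900, 3.0), t_start=-200.0)
        res = cr_correlation([rate], [np.ones(900)], [True], 500.0)
        assert res.n_excluded == 1
        assert res.n_cr_trials == 0

    def test_recovers_generator_snr_set_correlation(self):
        """Coupled generator: MLI rate carries the CR shape; mean r over
        many CR trials reflects that coupling (strongly positive)."""
        spec = synth.SessionGenSpec(n_trials=120, cr_probability=1.0,
                                    mli_burst_height=4.0, rate_noise_sd=0.05,
                                    baseline_epoch_ms=1000, seed=9)
        data = synth.gen_session_data(spec)
        rates = [instantaneous_rate(tr, duration=2500, t_start=-200.0)
                 for tr in data["mli_trials"]]
        res = cr_correlation(rates, data["eyelid_mm"], data["cr_flags"],
                             us_onset_ms=500.0)
        assert res.n_cr_trials > 100
        assert res.mean_r > 0.5


class TestMixtureFit:
    def test_recovers_planted_two_component_means(self):
        vals, _ = synth.gen_mixture_sample(means=(-0.05, 0.43),
                                           sds=(0.15, 0.15),
                                           weights=(0.9, 0.1), n=800, seed=1)
        fit = fit_two_gaussian_mixture(vals)
        assert fit.means[0] == pytest.approx(-0.05, abs=0.05)
        assert fit.means[1] == pytest.approx(0.43, abs=0.05)
        assert fit.skewness > 0
        assert fit.cutoff is not None and fit.cutoff > fit.means[0]

    def test_single_component_sample_degenerates(self):
        rng = np.random.default_rng(4)
        fit = fit_two_gaussian_mixture(rng.normal(0.1, 0.1, 500))
        # components collapse (or the posterior never separates): no cutoff
        assert fit.cutoff is None

    def test_cutoff_classification_at_0_43(self):
        vals, _ = synth.gen_mixture_sample(n=800, seed=2)
        labels = classify_putative_pcmli(vals, cutoff=0.43)
        assert np.array_equal(labels, vals >= 0.43)

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_two_gaussian_mixture(np.zeros(10))

    def test_mean_recovery_improves_with_sample_size(self):
        errs = []
        for n in (200, 2000):
            e = []
            for seed in range(5):
                vals, _ = synth.gen_mixture_sample(n=n, seed=seed)
                fit = fit_two_gaussian_mixture(vals)
                e.append(abs(fit.means[0] + 0.05) + abs(fit.means[1] - 0.43))
            errs.append(np.mean(e))
        assert errs[1] < errs[0]


def _poisson_epochs(rate_hz, n_epochs, length_ms, rng):
    out = []
    for _ in range(n_epochs):
        n = rng.poisson(rate_hz * length_ms / 1000)
        out.append(np.sort(rng.uniform(0, length_ms, n)))
    return out


class TestSpikeTriggeredCorrelogram:
    def test_independent_trains_not_significant(self):
        rng = np.random.default_rng(0)
        flags = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = SpikeTrain("a", baseline_epochs=_poisson_epochs(50, 4, 10000, r))
            b = SpikeTrain("b", baseline_epochs=_poisson_epochs(30, 4, 10000, r))
            res = spike_triggered_correlogram(a, b, n_shuffles=100, rng=rng)
            flags.append(res.significant)
            assert np.nanmean(res.norm_counts) == pytest.approx(1.0, abs=0.1)
        assert sum(flags) <= 1

    def test_inhibitory_coupling_gives_significant_trough(self):
        spec = synth.SessionGenSpec(n_trials=6, coupling_magnitude=0.9,
                                    coupling_lag_ms=2.0,
                                    coupling_duration_ms=5.0, seed=3)
        data = synth.gen_session_data(spec)
        a = SpikeTrain("pc", baseline_epochs=data["pc_baseline_epochs"])
        b = SpikeTrain("mli", baseline_epochs=data["mli_baseline_epochs"])
        res = spike_triggered_correlogram(a, b, n_shuffles=150,
                                          rng=np.random.default_rng(1))
        assert res.significant
        post = (res.lags >= 2) & (res.lags <= 7)
        assert res.z[post].min() <= -3.34           # trough after the spike
        assert np.nanmean(res.norm_counts[post]) < 1.0

    def test_shuffled_triggers_abolish_significance(self):
        spec = synth.SessionGenSpec(n_trials=6, coupling_magnitude=0.9,
                                    coupling_duration_ms=5.0, seed=3)
        data = synth.gen_session_data(spec)
        rng = np.random.default_rng(5)
        shuffled = []
        for ep in data["pc_baseline_epochs"]:
            isis = np.diff(ep)
            shuffled.append(ep[0] + np.concatenate([[0], np.cumsum(
                rng.permutation(isis))]))
        a = SpikeTrain("pc_shuf", baseline_epochs=shuffled)
        b = SpikeTrain("mli", baseline_epochs=data["mli_baseline_epochs"])
        res = spike_triggered_correlogram(a, b, n_shuffles=150, rng=rng)
        assert not res.significant

    def test_swapping_trains_mirrors_the_correlogram(self):
        rng = np.random.default_rng(7)
        a = SpikeTrain("a", baseline_epochs=_poisson_epochs(60, 3, 10000, rng))
        b = SpikeTrain("b", baseline_epochs=_poisson_epochs(40, 3, 10000, rng))
        r_ab = spike_triggered_correlogram(a, b, n_shuffles=100,
                                           rng=np.random.default_rng(0))
        r_ba = spike_triggered_correlogram(b, a, n_shuffles=100,
                                           rng=np.random.default_rng(0))
        # raw counts mirror exactly up to edge effects of the binning
        assert np.corrcoef(r_ab.counts, r_ba.counts[::-1])[0, 1] > 0.95

    def test_too_few_trigger_spikes_rejected(self):
        a = SpikeTrain("a", baseline_epochs=[np.array([1.0])])
        b = SpikeTrain("b", baseline_epochs=[np.array([2.0, 3.0])])
        with pytest.raises(InsufficientDataError):
            spike_triggered_correlogram(a, b, rng=np.random.default_rng(0))


class TestEventTriggers:
    def test_percentile_selection_matches_exhaustive_sort(self):
        """20 inter-spike intervals of 1..20 ms at the 35th percentile:
        the 7 longest (>= 14 ms) intervals are pauses."""
        times = np.concatenate([[0.0], np.cumsum(np.arange(1.0, 21.0))])
        starts = select_extreme_isi_starts(times, 0.35, largest=True)
        isis = np.diff(times)
        expected = times[:-1][isis >= 14.0]
        assert np.array_equal(starts, expected)
        assert len(starts) == 7
        bursts = select_extreme_isi_starts(times, 0.35, largest=False)
        assert np.array_equal(bursts, times[:-1][isis <= 7.0])

    def test_constant_isi_train_has_no_extremes(self):
        times = np.arange(0.0, 200.0, 10.0)
        assert select_extreme_isi_starts(times, 0.35, True).size == 0
        assert select_extreme_isi_starts(times, 0.35, False).size == 0

    def test_pause_triggered_increase_detected(self):
        """Inhibitory per-spike coupling: target rate recovers during
        trigger silences, so pause-triggered correlograms rise after 0."""
        spec = synth.SessionGenSpec(n_trials=6, coupling_magnitude=0.85,
                                    coupling_duration_ms=8.0,
                                    pc_baseline_hz=80.0, seed=13)
        data = synth.gen_session_data(spec)
        a = SpikeTrain("pc", baseline_epochs=data["pc_baseline_epochs"])
        b = SpikeTrain("mli", baseline_epochs=data["mli_baseline_epochs"])
        res = event_triggered_correlogram(a, b, event="pause", percentile=0.35,
                                          n_shuffles=120,
                                          rng=np.random.default_rng(2))
        post = res.lags > 0
        pre = res.lags < 0
        assert np.nanmean(res.norm_counts[post]) > np.nanmean(res.norm_counts[pre])

    def test_insufficient_intervals_rejected(self):
        a = SpikeTrain("a", baseline_epochs=[np.arange(0.0, 50.0, 10.0)])
        b = SpikeTrain("b", baseline_epochs=[np.arange(0.0, 50.0, 7.0)])
        with pytest.raises(InsufficientDataError):
            event_triggered_correlogram(a, b, rng=np.random.default_rng(0))


class TestPreCrFraction:
    def _trace(self, values, t_start=-200.0):
        return RateTrace(np.asarray(values, dtype=float), t_start=t_start)

    def test_pc_complete_before_onset_mli_after(self):
        t = np.arange(900) - 200.0
        pc = np.where(t < 100, np.where(t < 0, 60.0, 60.0 - 0.6 * np.clip(t, 0, 100)),
                      0.0)
        mli = np.where(t < 250, 20.0, 20.0 + np.clip(t - 250, 0, 150))
        res = pre_cr_fraction(self._trace(pc), self._trace(mli),
                              cr_onset_ms=250.0, isi=500.0)
        assert res.delta_pc == pytest.approx(1.0)
        assert res.delta_mli == pytest.approx(0.0, abs=0.01)
        assert res.difference == pytest.approx(1.0, abs=0.01)

    def test_both_changing_from_onset_gives_zero(self):
        t = np.arange(900) - 200.0
        ramp = np.clip(t - 250, 0, None)
        pc = 60.0 - 0.2 * ramp
        mli = 20.0 + 0.2 * ramp
        res = pre_cr_fraction(self._trace(pc), self._trace(mli), 250.0, 500.0)
        assert res.delta_pc == pytest.approx(0.0, abs=0.01)
        assert res.delta_mli == pytest.approx(0.0, abs=0.01)

    def test_late_onset_trials_excluded(self):
        r = self._trace(np.full(900, 10.0))
        with pytest.raises(InsufficientDataError):
            pre_cr_fraction(r, r, cr_onset_ms=420.0, isi=500.0)

    def test_generator_pc_lead_yields_positive_mean_difference(self):
        spec = synth.SessionGenSpec(n_trials=100, cr_probability=1.0,
                                    pc_lead_ms=60.0, rate_noise_sd=0.05,
                                    baseline_epoch_ms=1000, seed=21)
        data = synth.gen_session_data(spec)
        diffs = []
        for i, onset in enumerate(data["ground_truth"]["cr_onsets"]):
            pc = instantaneous_rate(data["pc_trials"][i], 2500, t_start=-200.0)
            mli = instantaneous_rate(data["mli_trials"][i], 2500, t_start=-200.0)
            try:
                res = pre_cr_fraction(pc, mli, onset, 500.0)
            except InsufficientDataError:
                continue
            diffs.append(res.difference)
        assert len(diffs) > 50
        assert np.mean(diffs) > 0.05


class TestGrouping:
    def test_equal_split_and_remainder_rule(self):
        onsets = np.arange(90, dtype=float)
        traces = {"eyelid": np.zeros((90, 10))}
        groups = group_trials(onsets, traces, 3)
        assert [len(g["trials"]) for g in groups] == [30, 30, 30]
        groups = group_trials(np.arange(91, dtype=float),
                              {"eyelid": np.zeros((91, 10))}, 3)
        assert [len(g["trials"]) for g in groups] == [30, 30, 31]

    def test_non_cr_trials_form_their_own_group(self):
        vals = np.array([1.0, 2.0, np.nan, 3.0, np.nan, 4.0])
        groups = group_trials(vals, {"x": np.zeros((6, 4))}, 2)
        assert groups[-1]["label"] == "non_cr"
        assert set(groups[-1]["trials"]) == {2, 4}

    def test_recovers_distinct_onset_cluster_means(self):
        rng = np.random.default_rng(8)
        centers = [150.0, 250.0, 350.0]
        onsets = np.concatenate([rng.normal(c, 5, 30) for c in centers])
        trace = onsets[:, None] * np.ones((1, 5))
        groups = group_trials(onsets, {"m": trace}, 3)
        means = [g["m"]["mean"][0] for g in groups[:3]]
        assert np.allclose(sorted(means), centers, atol=10)

    def test_too_few_cr_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_trials(np.array([1.0]), {"x": np.zeros((1, 2))}, 3)


def test_distribution_comparison_draws_and_tests():
    from cerloop.spikes import compare_correlation_distributions
    rng = np.random.default_rng(0)
    sim = rng.normal(0.0, 0.1, 500)
    same = rng.normal(0.0, 0.1, 64)
    shifted = rng.normal(0.5, 0.1, 64)
    p_same = compare_correlation_distributions(sim, same, n_draws=200,
                                               test="ks", rng=rng)
    p_diff = compare_correlation_distributions(sim, shifted, n_draws=200,
                                               test="ks", rng=rng)
    assert np.median(p_diff) < 0.001
    assert np.median(p_same) > 0.01
    p_t = compare_correlation_distributions(sim, shifted, n_draws=50,
                                            test="t", rng=rng)
    assert np.median(p_t) < 0.001
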