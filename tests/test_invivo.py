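"""Single-unit classification: binning, drug response, PSTH, optotagging,
waveform similarity, and dyskinesia correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyskpipe.invivo import (
    SessionEvents,
    SpikeTrain,
    WaveformThresholds,
    bin_firing,
    classify_drug_response,
    classify_population,
    classify_waveform,
    compute_psth,
    dyskinesia_correlation,
    optotag,
    waveform_similarity_test,
)
from dyskpipe.synthdata import SynthConfig, gen_session, gen_tagging_units


def _train(times, **kw):
    return SpikeTrain(unit_id="u", spike_times=np.asarray(times, dtype=float), **kw)


class TestSpikeTrainValidation:
    def test_sub_millisecond_isi_invalidates_unit(self):
        with pytest.raises(ValueError):
            _train([0.0, 0.0005])

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            _train([1.0, 0.5])


class TestBinFiring:
    def test_empty_train_gives_zero_bins(self):
        rates = bin_firing(_train([]), bin_s=60.0, t_start=0.0, t_end=300.0)
        assert (rates["rate_hz"] == 0).all()
        assert len(rates) == 5

    def test_even_rate_example(self):
        times = np.arange(120) * 0.5 + 0.25
        rates = bin_firing(_train(times), bin_s=60.0, t_start=0.0, t_end=60.0)
        assert len(rates) == 1
        assert rates["rate_hz"].iloc[0] == pytest.approx(2.0)

    def test_rate_times_width_conserves_spike_count(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 137.0, size=400))
        times = times[np.concatenate([[True], np.diff(times) >= 0.001])]
        rates = bin_firing(_train(times), bin_s=60.0, t_start=0.0, t_end=137.0)
        widths = np.diff(np.append(rates["bin_start_s"].to_numpy(), 137.0))
        assert np.sum(rates["rate_hz"] * widths) == pytest.approx(times.size)


class TestDrugResponse:
    @staticmethod
    def _rates(baseline_hz, post_hz, rng=None):
        # 70 one-minute bins: injection at 1800 s, post window 10-40 min
        t = np.arange(70) * 60.0
        if rng is None:
            rate = np.where(t < 1800, baseline_hz, post_hz).astype(float)
        else:
            lam = np.where(t < 1800, baseline_hz, post_hz) * 60.0
            rate = rng.poisson(lam) / 60.0
        return pd.DataFrame({"bin_start_s": t, "rate_hz": rate})

    def test_identical_constant_rates_are_nc(self):
        cls, p = classify_drug_response(self._rates(2.0, 2.0), 1800.0)
        assert cls == "NC"

    def test_gain_increase_is_on(self):
        rng = np.random.default_rng(1)
        cls, p = classify_drug_response(self._rates(2.0, 10.0, rng), 1800.0)
        assert cls == "On" and p < 0.01

    def test_gain_decrease_is_off(self):
        rng = np.random.default_rng(2)
        cls, p = classify_drug_response(self._rates(2.0, 0.4, rng), 1800.0)
        assert cls == "Off" and p < 0.01

    def test_type_one_error_near_alpha_on_null_units(self):
        rng = np.random.default_rng(4)
        hits = sum(
            classify_drug_response(self._rates(2.0, 2.0, rng), 1800.0)[0] != "NC"
            for _ in range(300)
        )
        assert hits / 300 <= 0.03

    def test_uncovered_window_raises(self):
        rates = pd.DataFrame({"bin_start_s": np.arange(10) * 60.0,
                              "rate_hz": np.ones(10)})
        with pytest.raises(ValueError, match="baseline"):
            classify_drug_response(rates, 1800.0)


class TestWaveformClass:
    def test_wide_waveform_is_msn(self):
        assert classify_waveform(1000.0, 300.0) == "MSN"

    def test_narrow_waveform_is_in(self):
        assert classify_waveform(250.0, 75.0) == "IN"

    def test_boundary_equality_is_msn(self):
        thr = WaveformThresholds()
        assert classify_waveform(thr.peak_to_valley_us, thr.peak_width_us) == "MSN"
        assert classify_waveform(thr.peak_to_valley_us - 1, thr.peak_width_us) == "MSN"

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            classify_waveform(np.nan, 100.0)


class TestPsth:
    def test_empty_train_zero_psth(self):
        psth = compute_psth(_train([]), np.array([10.0, 20.0]))
        assert (psth.rate_hz == 0).all()

    def test_spike_at_every_onset_fills_one_bin(self):
        events = np.arange(10.0, 110.0, 1.0)
        psth = compute_psth(_train(events), events, window_ms=(-50, 50), bin_ms=1.0)
        at_zero = np.flatnonzero(psth.bin_left_ms == 0.0)[0]
        assert psth.rate_hz[at_zero] == pytest.approx(1000.0)
        assert psth.rate_hz.sum() == pytest.approx(1000.0)

    def test_merged_event_sets_are_weighted_mean(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 100, 300))
        times = times[np.concatenate([[True], np.diff(times) >= 0.001])]
        train = _train(times)
        ev1 = np.arange(5.0, 45.0, 1.0)
        ev2 = np.arange(50.0, 70.0, 1.0)
        merged = compute_psth(train, np.concatenate([ev1, ev2]), window_ms=(-100, 100))
        p1 = compute_psth(train, ev1, window_ms=(-100, 100))
        p2 = compute_psth(train, ev2, window_ms=(-100, 100))
        weighted = (p1.rate_hz * ev1.size + p2.rate_hz * ev2.size) / (ev1.size + ev2.size)
        np.testing.assert_allclose(merged.rate_hz, weighted, atol=1e-9)

    def test_matches_brute_force_double_loop(self):
        # oracle: explicit loop over events and spikes
        rng = np.random.default_rng(6)
        for _ in range(100):
            times = np.sort(rng.uniform(0, 50, rng.integers(0, 200)))
            times = times[np.concatenate([[True], np.diff(times) >= 0.001])] \
                if times.size else times
            events = np.sort(rng.uniform(5, 45, rng.integers(1, 20)))
            psth = compute_psth(_train(times), events, window_ms=(-200, 200), bin_ms=5.0)
            edges = psth.bin_edges_ms
            counts = np.zeros(len(edges) - 1)
            for ev in events:
                for s in times:
                    rel = (s - ev) * 1000.0
                    for k in range(len(edges) - 1):
                        if edges[k] <= rel < edges[k + 1]:
                            counts[k] += 1
            oracle = counts / (events.size * 5.0 / 1000.0)
            np.testing.assert_allclose(psth.rate_hz, oracle, atol=1e-9)

    def test_requires_events(self):
        with pytest.raises(ValueError):
            compute_psth(_train([1.0]), np.array([]))


class TestOptotag:
    def test_tagged_unit_identified(self):
        cfg = SynthConfig(seed=11, pulses_per_power=150)
        trains, events = gen_tagging_units(cfg, 5, tagged=True)
        results = [optotag(t, events) for t in trains]
        assert all(r.identified for r in results)
        assert all(r.onset_latency_ms <= 15.0 for r in results)

    def test_long_latency_fails_first_criterion(self):
        cfg = SynthConfig(seed=12, pulses_per_power=150)
        trains, events = gen_tagging_units(cfg, 5, tagged=True, latency_ms=25.0)
        for t in trains:
            res = optotag(t, events)
            assert not res.crit1_latency_ok
            assert not res.identified

    def test_uncoupled_poisson_units_rejected(self):
        cfg = SynthConfig(seed=13, pulses_per_power=150)
        trains, events = gen_tagging_units(cfg, 30, tagged=False)
        assert sum(optotag(t, events).identified for t in trains) == 0

    def test_no_pulses_raises(self):
        events = SessionEvents(injection_time_s=0.0, session_start_s=0.0,
                               session_end_s=10.0)
        with pytest.raises(ValueError):
            optotag(_train([1.0]), events)


class TestWaveformSimilarity:
    @staticmethod
    def _waveforms(rng, n=60):
        tpl = np.sin(np.linspace(0, 3 * np.pi, 48))
        return tpl + rng.normal(0, 0.3, size=(n, 48))

    def test_identical_sets_pass(self, rng):
        wf = self._waveforms(rng)
        ok, _ = waveform_similarity_test(wf, wf.copy())
        assert ok

    def test_bootstrap_null_pass_rate_matches_alpha(self, rng):
        # evoked drawn by resampling spontaneous: pass rate ~ 1 - alpha
        passes = 0
        n_runs = 500
        for _ in range(n_runs):
            spont = self._waveforms(rng)
            evoked = spont[rng.integers(0, spont.shape[0], size=spont.shape[0])]
            evoked = evoked + rng.normal(0, 0.3, size=evoked.shape)
            ok, _ = waveform_similarity_test(spont, evoked, alpha=0.01)
            passes += ok
        assert passes / n_runs > 0.95

    def test_large_shift_on_first_axis_fails(self, rng):
        spont = self._waveforms(rng)
        pooled_sd = spont.std()
        evoked = spont + 5 * pooled_sd  # uniform offset loads on a leading PC
        ok, p = waveform_similarity_test(spont, evoked)
        assert not ok
        assert p < 1e-6


class TestDyskCorrelation:
    def test_perfectly_linear_rate_is_dysk(self):
        aim = np.tile(np.arange(6.0), 10)
        r2, slope, cls = dyskinesia_correlation(3.0 * aim, aim)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(3.0)
        assert cls == "DYSK"

    def test_threshold_is_strict(self):
        aim = np.tile(np.arange(6.0), 10)
        # perfect fit with the threshold raised to R^2 = 1: strict > gives ON
        r2, _, cls = dyskinesia_correlation(3.0 * aim, aim, r2_threshold=1.0)
        assert r2 == pytest.approx(1.0)
        assert cls == "ON"

    def test_null_units_rarely_cross_threshold(self, rng):
        r2s = []
        for _ in range(100):
            aim = rng.integers(0, 13, size=60).astype(float)
            rate = rng.poisson(120, size=60) / 60.0
            r2, _, cls = dyskinesia_correlation(rate, aim)
            r2s.append(r2)
        assert np.median(r2s) < 0.1

    def test_missing_minutes_excluded(self):
        aim = np.array([0, 1, 2, 3, 4, 5, np.nan, np.nan] * 3)
        rate = np.where(np.isfinite(aim), 2.0 * aim, 99.0)
        r2, slope, cls = dyskinesia_correlation(rate, aim)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            dyskinesia_correlation(np.arange(5.0), np.arange(5.0))

    def test_zero_aim_variance_is_on_with_warning(self):
        with pytest.warns(UserWarning):
            r2, _, cls = dyskinesia_correlation(np.arange(12.0), np.zeros(12))
        assert np.isnan(r2)
        assert cls == "ON"


class TestClassifyPopulation:
    def test_empty_population(self):
        events = SessionEvents(injection_time_s=1800.0, session_start_s=0.0,
                               session_end_s=4200.0)
        table, props = classify_population([], events)
        assert table.empty
        assert props.empty

    def test_recovery_on_synthetic_session(self):
        cfg = SynthConfig(seed=21, n_units=60, pulses_per_power=100)
        trains, events, labels, aim = gen_session(cfg)
        from dyskpipe.behavior import bin_aim

        aim_bins = bin_aim(aim, bin_min=1.0)
        table, props = classify_population(trains, events, aim_bins)
        assert props.sum() == pytest.approx(1.0)
        merged = table.merge(labels, on="unit_id")
        # IN units share the NC drug profile; compare On/Off/NC expectation
        expected = merged["true_class"].replace({"IN": "NC"})
        accuracy = (merged["drug_class"] == expected).mean()
        assert accuracy >= 0.85
        # tagging recovered for the TRAPed (DYSK) units
        assert (merged["tagged"] == merged["true_tagged"]).mean() >= 0.9
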