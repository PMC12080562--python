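"""Synthetic-data generator: determinism, calibration and ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyskpipe.behavior import detect_rotations
from dyskpipe.expression import normalize_cells
from dyskpipe.synthdata import (
    SynthConfig,
    coupling_for_r2,
    gen_aim_trace,
    gen_cell_table,
    gen_rabies_tables,
    gen_session,
    gen_sweeps,
    gen_tracking,
    gen_unit_population,
    latent_trajectory,
)


class TestConfig:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SynthConfig(class_mix={"On": 0.5, "Off": 0.5, "NC": 0.5, "IN": 0.0})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(baseline_rate_hz=-1.0)

    def test_session_must_outlast_baseline(self):
        with pytest.raises(ValueError):
            SynthConfig(session_minutes=20.0, baseline_minutes=30.0)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"seed": 9, "n_units": 3, "on_gain": 4.0}))
        cfg = SynthConfig.from_yaml(path)
        assert (cfg.seed, cfg.n_units, cfg.on_gain) == (9, 3, 4.0)


class TestUnitPopulation:
    def test_empty_population(self):
        cfg = SynthConfig(seed=1, n_units=0, pulses_per_power=10)
        trains, events, labels = gen_unit_population(cfg)
        assert trains == []
        assert labels.empty
        assert events.session_end_s > events.injection_time_s

    def test_seed_determinism_byte_identical(self):
        cfg = SynthConfig(seed=1, n_units=6, pulses_per_power=20)
        out1 = gen_unit_population(cfg)
        out2 = gen_unit_population(cfg)
        for a, b in zip(out1[0], out2[0]):
            assert a.spike_times.tobytes() == b.spike_times.tobytes()
            assert a.spont_waveforms.tobytes() == b.spont_waveforms.tobytes()
        pd.testing.assert_frame_equal(out1[2], out2[2])

    def test_baseline_spike_count_matches_poisson_oracle(self):
        # 2 Hz x 1800 s baseline: mean count 3600, Poisson SD 60
        cfg = SynthConfig(seed=2, n_units=24, pulses_per_power=0,
                          class_mix={"On": 0.0, "Off": 0.0, "NC": 1.0, "IN": 0.0})
        trains, events, _ = gen_unit_population(cfg, include_laser_epoch=False)
        counts = [np.sum(t.spike_times < events.injection_time_s) for t in trains]
        expected, sd = 3600.0, 60.0
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(len(counts))

    def test_trains_sorted_refractory_nonnegative(self):
        cfg = SynthConfig(seed=3, n_units=8, pulses_per_power=20)
        trains, _, _ = gen_unit_population(cfg)
        for t in trains:
            assert np.all(t.spike_times >= 0)
            if t.n_spikes > 1:
                isi = np.diff(t.spike_times)
                assert np.all(isi >= 0.001 - 1e-12)

    def test_labels_cover_every_unit_once(self):
        cfg = SynthConfig(seed=4, n_units=15, pulses_per_power=0)
        trains, _, labels = gen_unit_population(cfg, include_laser_epoch=False)
        assert sorted(labels["unit_id"]) == sorted(t.unit_id for t in trains)
        assert labels["unit_id"].is_unique

    def test_dysk_units_are_the_tagged_ones(self):
        cfg = SynthConfig(seed=5, n_units=30, pulses_per_power=0)
        _, _, labels = gen_unit_population(cfg, include_laser_epoch=False)
        assert (labels["true_dysk"] == labels["true_tagged"]).all()
        assert labels.loc[labels["true_dysk"], "true_class"].eq("On").all()


class TestAimTrace:
    def test_zero_latent_zero_noise_gives_all_zero(self):
        cfg = SynthConfig(seed=1, aim_noise_sd=0.0)
        aim = gen_aim_trace(cfg, np.zeros(30))
        assert np.all(aim.total == 0)

    def test_saturated_latent_hits_ceiling(self):
        cfg = SynthConfig(seed=1, aim_noise_sd=0.0)
        aim = gen_aim_trace(cfg, np.ones(30))
        assert np.all(aim.total == 12)

    def test_ramp_latent_monotone_in_rank(self):
        cfg = SynthConfig(seed=1, aim_noise_sd=0.0)
        latent = np.linspace(0, 1, 100)
        aim = gen_aim_trace(cfg, latent)
        rho = stats.spearmanr(latent, aim.total).statistic
        assert rho > 0.9

    def test_latent_outside_unit_interval_rejected(self):
        cfg = SynthConfig(seed=1)
        with pytest.raises(ValueError):
            gen_aim_trace(cfg, np.array([0.5, 1.2]))


class TestTracking:
    def test_no_bias_no_noise_no_turns(self):
        cfg = SynthConfig(seed=1)
        track = gen_tracking(cfg, bias_rev_per_min=0.0, duration_s=120.0)
        m = detect_rotations(track)
        assert m.contra_quarter_turns == 0 and m.ipsi_quarter_turns == 0

    def test_one_rev_per_min_gives_four_quarter_turns_per_min(self):
        cfg = SynthConfig(seed=1)
        track = gen_tracking(cfg, bias_rev_per_min=1.0, duration_s=600.0)
        m = detect_rotations(track)
        assert m.contra_quarter_turns == 40
        assert m.ipsi_quarter_turns == 0

    def test_positions_stay_inside_arena(self):
        cfg = SynthConfig(seed=2)
        track = gen_tracking(cfg, bias_rev_per_min=0.5, duration_s=300.0,
                             heading_noise_sd=1.0)
        r = np.hypot(track.x, track.y)
        assert np.all(r <= track.arena_radius_cm + 1e-9)


class TestRabiesTables:
    def test_zero_means_give_zero_counts(self):
        cfg = SynthConfig(seed=1)
        tables = gen_rabies_tables(cfg, {"control": {}}, n_animals_per_condition=3,
                                   region_means={"MOp": 0.0, "GPe": 0.0})
        for t in tables:
            assert all(c == 0 for c in t.counts.values())

    def test_doubled_cortical_mean_recovered_over_many_animals(self):
        from dyskpipe.connectivity import load_default_ontology, relative_number

        cfg = SynthConfig(seed=2)
        onto = load_default_ontology()
        tables = gen_rabies_tables(
            cfg, {"control": {}, "LID": {"MOp": 2.0, "MOs": 2.0, "SSp": 2.0, "SSs": 2.0,
                                         "ORB": 2.0, "CLA": 2.0}},
            n_animals_per_condition=50,
        )
        by_cond = {}
        for cond in ("control", "LID"):
            vals = [relative_number(t, "CTX", onto) for t in tables if t.condition == cond]
            by_cond[cond] = np.mean(vals)
        assert by_cond["LID"] / by_cond["control"] == pytest.approx(2.0, rel=0.1)

    def test_same_seed_identical_tables(self):
        cfg = SynthConfig(seed=3)
        t1 = gen_rabies_tables(cfg, {"control": {}, "Park": {}})
        t2 = gen_rabies_tables(cfg, {"control": {}, "Park": {}})
        for a, b in zip(t1, t2):
            assert a.counts == b.counts
            assert a.striatal_starters == b.striatal_starters


class TestCellTable:
    def test_areas_strictly_positive(self):
        cells = gen_cell_table(SynthConfig(seed=1), n_cells=200)
        assert (cells["area_um2"] > 0).all()

    def test_null_enrichment_gives_matched_classes(self):
        cells = gen_cell_table(SynthConfig(seed=2), enrichment={}, n_cells=2000,
                               n_slices=8)
        norm = normalize_cells(cells)
        trap_mean = norm.loc[norm["true_trap"], "drd1_norm"].mean()
        untrap_mean = norm.loc[~norm["true_trap"], "drd1_norm"].mean()
        assert trap_mean == pytest.approx(untrap_mean, rel=0.1)

    def test_fold_enrichment_recovered(self):
        # lognormal mean oracle: fold multiplies the TRAP-class mean exactly
        cells = gen_cell_table(SynthConfig(seed=3), enrichment={"drd1": 1.5},
                               n_cells=500, n_slices=5)
        norm = normalize_cells(cells)  # slice normalization removes staining factors
        ratio = (norm.loc[norm["true_trap"], "drd1_norm"].mean()
                 / norm.loc[~norm["true_trap"], "drd1_norm"].mean())
        assert ratio == pytest.approx(1.5, abs=0.1)

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError):
            gen_cell_table(SynthConfig(seed=1), enrichment={"drd1": 0.0})


class TestSweeps:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            gen_sweeps(SynthConfig(seed=1), "voltage-ramp")

    def test_mepsc_event_count_matches_poisson_oracle(self):
        # 2 Hz x 300 s: 600 expected events, Poisson SD ~24.5
        sw = gen_sweeps(SynthConfig(seed=4), "mepsc", rate_hz=2.0, duration_s=300.0)
        n = sw.ground_truth["event_times_s"].size
        assert abs(n - 600) < 3 * np.sqrt(600) + 15  # small loss to overlap thinning

    def test_step_spike_counts_monotone_at_zero_noise(self):
        sw = gen_sweeps(SynthConfig(seed=5), "steps", noise_sd_mv=0.0)
        counts = sw.ground_truth["spike_counts"]
        assert np.all(np.diff(counts) >= 0)

    def test_sweep_csv_round_trip(self, tmp_path):
        sw = gen_sweeps(SynthConfig(seed=6), "optical", n_reps=2)
        sw.to_csv(tmp_path / "sweeps.csv", tmp_path / "meta.json")
        from dyskpipe.slicephys import SweepSet

        back = SweepSet.from_csv(tmp_path / "sweeps.csv", tmp_path / "meta.json")
        assert back.n_sweeps == sw.n_sweeps
        assert back.sample_rate_hz == sw.sample_rate_hz
        np.testing.assert_allclose(back.traces, sw.traces, atol=1e-6)


class TestCouplingCalibration:
    def test_coupling_formula_matches_simulated_r2(self):
        # simulate binned Poisson rates at the calibrated coupling and check
        # the achieved R^2 against the construction target
        rng = np.random.default_rng(11)
        latent = latent_trajectory(SynthConfig(seed=1), np.arange(60) + 0.5)
        target, r0 = 0.6, 10.0
        b = coupling_for_r2(target, latent, r0)
        r2s = []
        for _ in range(200):
            rates = r0 + b * (latent - latent.mean())
            y = rng.poisson(rates * 60) / 60.0
            r2s.append(stats.linregress(latent, y).rvalue ** 2)
        assert np.mean(r2s) == pytest.approx(target, abs=0.06)

    def test_zero_variance_latent_gives_zero_coupling(self):
        assert coupling_for_r2(0.5, np.ones(10), 5.0) == 0.0


def test_gen_session_bundle_is_consistent():
    cfg = SynthConfig(seed=8, n_units=4, pulses_per_power=10)
    trains, events, labels, aim = gen_session(cfg)
    assert len(trains) == 4
    # every-other-minute cadence over the post-injection span
    assert np.all(np.diff(aim.t_min) == pytest.approx(2.0))
    assert aim.t_min.size == (cfg.session_minutes - cfg.baseline_minutes) / 2
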