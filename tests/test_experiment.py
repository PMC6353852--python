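import numpy as np
import pandas as pd
import pytest

from bayemo import (
    ConditionMapping,
    ConfigurationError,
    EmptyGroupError,
    ErpConfig,
    ErpEpoch,
    ExperimentConfig,
    InvalidParameterError,
    LikertConfig,
    StimulusCondition,
    average_erp,
    build_schedule,
    condition_params,
    crossover_point,
    extract_p300,
    extract_p300_batch,
    run_experiment,
    simulate_likert,
    synthesize_epoch,
)
from bayemo.experiment import DEFAULT_STIMULI


class TestSchedule:
    def test_main_session_trial_total(self):
        # 8 videos x 20 presentation sets = 160 trials per subject
        sched = build_schedule(n_sets=20, n_subjects=1, seed=0)
        assert len(sched) == 160
        sched9 = build_schedule(n_sets=20, n_subjects=9, seed=0)
        assert len(sched9) == 9 * 160

    def test_sound_only_session_trial_total(self):
        # 8 sounds x 5 presentation sets = 40 trials per subject
        sched = build_schedule(n_sets=5, n_subjects=1, seed=0)
        assert len(sched) == 40

    def test_each_set_is_a_permutation_of_the_stimuli(self):
        sched = build_schedule(n_sets=6, n_subjects=3, seed=11)
        labels = sorted(s.instrument_label for s in DEFAULT_STIMULI)
        for (_, _), block in sched.trials.groupby(["subject_id", "presentation_set"]):
            assert sorted(block["instrument"]) == labels

    def test_isi_range_and_mean(self):
        sched = build_schedule(n_sets=200, n_subjects=5, seed=2)
        isi = sched.trials["isi_ms"]
        assert ((isi >= 1000.0) & (isi <= 2000.0)).all()
        assert isi.mean() == pytest.approx(1500.0, abs=15.0)

    def test_reproducible_per_seed(self):
        a = build_schedule(n_sets=4, n_subjects=2, seed=5).to_frame()
        b = build_schedule(n_sets=4, n_subjects=2, seed=5).to_frame()
        assert a.equals(b)

    def test_empty_stimulus_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_schedule(stimuli=[], seed=0)


class TestConditionMapping:
    def test_default_lookup(self):
        cond = StimulusCondition("A", "X", "clave/clave")
        assert condition_params(cond) == (0.2, 0.0)
        cond = StimulusCondition("B", "Y", "jawbone/vibraphone")
        assert condition_params(cond) == (1.0, 2.0)

    def test_gain_table_shows_crossover_pattern(self):
        g = ConditionMapping().gain_table()
        assert g["BX"] > g["AX"]  # more uncertainty wins at zero error
        assert g["AY"] > g["BY"]  # less uncertainty wins at large error

    def test_incongruent_delta_exceeds_crossover(self):
        m = ConditionMapping()
        dstar = crossover_point(m.s_p_familiar, m.s_p_unfamiliar, m.s_l).delta_star
        assert m.delta_incongruent > dstar

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"s_p_familiar": 1.0, "s_p_unfamiliar": 0.2},  # uncertainty order
            {"delta_congruent": 2.0, "delta_incongruent": 1.0},  # error order
            {"delta_incongruent": 0.5},  # below the crossover point
            {"s_l": 2.0},  # kills the crossover entirely
        ],
    )
    def test_invalid_mappings_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ConditionMapping(**kwargs)


class TestLikert:
    def test_noise_free_ratings_constant_and_ordered_by_gain(self):
        sched = build_schedule(n_sets=3, n_subjects=2, seed=1)
        cfg = LikertConfig(response_noise_sd=0.0, subject_sd=0.0)
        out = simulate_likert(sched, config=cfg, seed=0)
        per_cell = out.groupby("condition")["rating"].agg(["min", "max", "mean"])
        assert (per_cell["min"] == per_cell["max"]).all()  # constant within cell
        gains = ConditionMapping().gain_table()
        order = sorted(gains, key=gains.get)
        means = [per_cell.loc[c, "mean"] for c in order]
        assert means == sorted(means)
        assert len(set(means)) == 4

    def test_ratings_in_range(self):
        sched = build_schedule(n_sets=5, n_subjects=3, seed=4)
        out = simulate_likert(sched, seed=9)
        assert out["rating"].isin([1, 2, 3, 4]).all()

    def test_reproducible_per_seed(self):
        sched = build_schedule(n_sets=2, n_subjects=2, seed=3)
        a = simulate_likert(sched, seed=42)
        b = simulate_likert(sched, seed=42)
        assert a.equals(b)

    def test_condition_means_show_crossover_pattern(self):
        sched = build_schedule(n_sets=20, n_subjects=9, seed=8)
        out = simulate_likert(sched, seed=8)
        m = out.groupby(["familiarity", "congruity"])["rating"].mean()
        assert m.loc["B", "X"] > m.loc["A", "X"]
        assert m.loc["A", "Y"] > m.loc["B", "Y"]


class TestEpochRoundTrip:
    def test_noise_free_synthesis_recovers_peak_exactly(self, quiet_erp):
        cfg = ErpConfig(
            p300_latency_sd_ms=0.0, noise_sd_uv=0.0,
            amplitude_base_uv=10.0, amplitude_per_nat_uv=0.0,
        )
        epoch = synthesize_epoch(G=0.0, config=cfg, seed=0)
        m = extract_p300(epoch)
        assert not m.rejected
        assert m.amplitude_uv == 10.0
        assert m.latency_ms == 350.0

    def test_constant_offset_removed_by_baseline_correction(self):
        cfg = ErpConfig(p300_latency_sd_ms=0.0, noise_sd_uv=0.0)
        epoch = synthesize_epoch(G=1.0, config=cfg, seed=0)
        shifted = ErpEpoch(samples=epoch.samples + 5.0, config=cfg)
        a = extract_p300(epoch)
        b = extract_p300(shifted)
        assert b.amplitude_uv == pytest.approx(a.amplitude_uv, abs=1e-12)
        assert b.latency_ms == a.latency_ms

    def test_amplitude_increases_with_gain(self):
        cfg = ErpConfig(p300_latency_sd_ms=0.0, noise_sd_uv=0.0)
        amp = [
            extract_p300(synthesize_epoch(G=g, config=cfg, seed=0)).amplitude_uv
            for g in (0.0, 1.0, 3.0)
        ]
        assert amp[0] < amp[1] < amp[2]


class TestExtraction:
    def test_artifact_rejection_threshold(self):
        cfg = ErpConfig()
        samples = np.zeros(cfg.n_samples)
        samples[600] = 120.0
        m = extract_p300(ErpEpoch(samples=samples, config=cfg))
        assert m.rejected
        assert m.amplitude_uv is None and m.latency_ms is None

    def test_flat_epoch_yields_zero_amplitude_at_window_start(self):
        cfg = ErpConfig()
        m = extract_p300(ErpEpoch(samples=np.zeros(cfg.n_samples), config=cfg))
        assert not m.rejected
        assert m.amplitude_uv == 0.0
        assert m.latency_ms == 250.0  # earliest sample wins the tie

    def test_tie_break_earliest_latency(self):
        cfg = ErpConfig()
        samples = np.zeros(cfg.n_samples)
        t = cfg.times_ms()
        i_late = int(np.nonzero(t == 1000.0)[0][0])  # 500 ms post-sound
        i_early = int(np.nonzero(t == 800.0)[0][0])  # 300 ms post-sound
        samples[i_late] = 7.0
        samples[i_early] = 7.0
        m = extract_p300(ErpEpoch(samples=samples, config=cfg))
        assert m.amplitude_uv == 7.0
        assert m.latency_ms == 300.0

    def test_batch_matches_single(self):
        cfg = ErpConfig()
        rng = np.random.default_rng(0)
        epochs = rng.normal(0, 5, size=(4, cfg.n_samples))
        batch = extract_p300_batch(epochs, cfg)
        for i in range(4):
            single = extract_p300(ErpEpoch(samples=epochs[i], config=cfg))
            assert single.amplitude_uv == pytest.approx(batch["amplitude_uv"][i])
            assert single.latency_ms == batch["latency_ms"][i]


class TestAverageErp:
    def _trials(self, n):
        return pd.DataFrame({"condition": ["AX"] * n})

    def test_identical_epochs_average_to_themselves(self):
        cfg = ErpConfig()
        epoch = np.sin(np.linspace(0, 6, cfg.n_samples))
        epochs = np.tile(epoch, (5, 1))
        means, counts = average_erp(epochs, self._trials(5), ["condition"], cfg)
        np.testing.assert_allclose(means.loc["AX"].to_numpy(), epoch)
        assert counts["AX"] == 5

    def test_symmetric_epochs_cancel(self):
        cfg = ErpConfig()
        epochs = np.vstack([np.ones(cfg.n_samples), -np.ones(cfg.n_samples)])
        means, _ = average_erp(epochs, self._trials(2), ["condition"], cfg)
        np.testing.assert_allclose(means.loc["AX"].to_numpy(), 0.0)

    def test_rejected_epochs_excluded_and_empty_group_raises(self):
        cfg = ErpConfig()
        good = np.ones(cfg.n_samples)
        bad = np.full(cfg.n_samples, 150.0)
        trials = pd.DataFrame({"condition": ["AX", "AX", "BY"]})
        means, counts = average_erp(np.vstack([good, bad, good]), trials,
                                    ["condition"], cfg)
        assert counts["AX"] == 1
        with pytest.raises(EmptyGroupError):
            average_erp(np.vstack([bad]), pd.DataFrame({"condition": ["AX"]}),
                        ["condition"], cfg)

    def test_grand_mean_shows_crossover_in_p300_window(self, small_experiment):
        res = run_experiment(small_experiment, seed=31, keep_epochs=True)
        means, _ = average_erp(res.epochs, res.p300, ["condition"],
                               small_experiment.erp)
        i0, i1 = small_experiment.erp.window_indices()
        peak = means.to_numpy()[:, i0:i1 + 1].max(axis=1)
        peaks = dict(zip(means.index, peak))
        assert peaks["BX"] > peaks["AX"]
        assert peaks["AY"] > peaks["BY"]


class TestRunExperiment:
    def test_reproducible_per_seed(self, small_experiment):
        a = run_experiment(small_experiment, seed=5)
        b = run_experiment(small_experiment, seed=5)
        assert a.p300.equals(b.p300)
        assert a.ratings.equals(b.ratings)

    def test_trial_count_invariant(self, small_experiment):
        res = run_experiment(small_experiment, seed=1)
        n = small_experiment.n_subjects * small_experiment.n_sets * 8
        assert len(res.p300) == n
        assert len(res.ratings) == n

    def test_cell_tables_are_balanced(self, small_experiment):
        res = run_experiment(small_experiment, seed=2)
        tab = res.p300_cell_table()
        assert len(tab) == small_experiment.n_subjects * 4
        counts = tab.groupby("subject_id").size()
        assert (counts == 4).all()

    def test_requires_seed(self, small_experiment):
        with pytest.raises(InvalidParameterError):
            run_experiment(small_experiment)
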