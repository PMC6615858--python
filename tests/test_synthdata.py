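"""Generator behavior: stimulus streams, tuning, mixing, eye traces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvinfo.containers import EpochedData, circular_difference
from mvinfo.synthdata import (
    CONFIG_A,
    CONFIG_B,
    ConfigurationError,
    MixingModel,
    PopulationConfig,
    StimulusConfig,
    generate_eye_traces,
    generate_stimulus_stream,
    mix_to_sensors,
    simulate_tuned_responses,
    temporal_kernel,
    tuning_function,
)


class TestStimulusStream:
    def test_config_a_onsets_and_positions(self):
        t = generate_stimulus_stream(CONFIG_A, 6, seed=0)
        assert len(t) == 6
        assert t["onset_time"].tolist() == [0, 200, 400, 600, 800, 1000]
        assert t["sequence_position"].tolist() == [1, 2, 3, 4, 5, 6]
        assert set(t["color_angle"]) <= set(CONFIG_A.class_angles)

    def test_config_b_soa_is_120ms(self):
        t = generate_stimulus_stream(CONFIG_B, 8, seed=0)
        assert np.allclose(np.diff(t["onset_time"]), 120.0)

    def test_same_seed_identical_tables(self):
        a = generate_stimulus_stream(CONFIG_B, 50, seed=7)
        b = generate_stimulus_stream(CONFIG_B, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusConfig(10, 100.0, 20.0, 8)

    def test_label_marginals_uniform(self):
        t = generate_stimulus_stream(CONFIG_B, 12000, seed=1)
        for col in ("color_angle", "motion_angle"):
            counts = t[col].value_counts()
            assert counts.size == 8
            p = 1.0 / 8
            se = np.sqrt(p * (1 - p) * 12000)
            assert np.all(np.abs(counts - 1500) < 3 * se)

    def test_onsets_strictly_increasing(self):
        t = generate_stimulus_stream(CONFIG_A, 100, seed=3)
        assert (np.diff(t["onset_time"]) > 0).all()


class TestTuningFunction:
    def test_unimodal_peaks_at_preferred(self):
        peak = tuning_function(90.0, 90.0, "unimodal", amplitude=2.0, baseline=0.5)
        assert peak == pytest.approx(2.5)
        assert tuning_function(120.0, 90.0, "unimodal") < tuning_function(90.0, 90.0)

    def test_bimodal_180_periodicity(self):
        a = tuning_function(30.0, 30.0, "bimodal")
        b = tuning_function(210.0, 30.0, "bimodal")
        assert a == pytest.approx(b, abs=1e-12)

    def test_untuned_returns_baseline(self):
        assert tuning_function(123.0, 0.0, "untuned", baseline=0.7) == 0.7

    def test_opposite_angle_value_frozen(self):
        # exp(kappa * (cos(pi) - 1)) = exp(-4) for kappa = 2
        val = tuning_function(180.0, 0.0, "unimodal", amplitude=1.0, kappa=2.0)
        assert val == pytest.approx(0.018315638888734179, abs=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(
        angle=st.floats(-720, 720),
        pref=st.floats(0, 360),
        kappa=st.floats(0.2, 8.0),
    )
    def test_periodicity_property(self, angle, pref, kappa):
        uni = tuning_function(angle, pref, "unimodal", kappa=kappa)
        assert uni == pytest.approx(
            tuning_function(angle + 360.0, pref, "unimodal", kappa=kappa), abs=1e-9
        )
        bim = tuning_function(angle, pref, "bimodal", kappa=kappa)
        assert bim == pytest.approx(
            tuning_function(angle + 180.0, pref, "bimodal", kappa=kappa), abs=1e-9
        )


class TestSimulateResponses:
    def test_untuned_noiseless_epochs_identical(self):
        trials = generate_stimulus_stream(CONFIG_B, 10, seed=0)
        pop = PopulationConfig(tuning_shape="untuned", noise_sd=0.0, baseline=0.3)
        ep = simulate_tuned_responses(trials, pop, seed=0)
        assert np.allclose(ep.data, ep.data[0])

    def test_preferred_label_gives_largest_peak(self):
        trials = generate_stimulus_stream(CONFIG_B, 200, seed=1)
        pop = PopulationConfig(tuned_feature="color", noise_sd=0.0, n_units=1)
        ep = simulate_tuned_responses(trials, pop, seed=2)
        pref = ep.channels["pref_angle"].iloc[0]
        peaks = ep.data[:, 0, :].max(axis=1)
        labels = ep.labels("color")
        dist = np.abs(circular_difference(labels, pref))
        best = labels[np.argmax(peaks)]
        assert np.abs(circular_difference(best, pref)) == dist.min()

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            simulate_tuned_responses(
                generate_stimulus_stream(CONFIG_B, 1, seed=0).iloc[:0],
                PopulationConfig(),
            )

    def test_seed_determinism(self):
        trials = generate_stimulus_stream(CONFIG_B, 20, seed=5)
        a = simulate_tuned_responses(trials, PopulationConfig(), seed=9)
        b = simulate_tuned_responses(trials, PopulationConfig(), seed=9)
        assert np.array_equal(a.data, b.data)

    def test_bimodal_population_axis_symmetric_at_zero_noise(self):
        pop = PopulationConfig(tuning_shape="bimodal", noise_sd=0.0, n_units=3)
        trials = pd.DataFrame(
            {
                "session_id": 0,
                "event_index": [0, 1],
                "onset_time": [0.0, 120.0],
                "sequence_position": [1, 2],
                "color_angle": [45.0, 225.0],  # opposite directions
                "motion_angle": [0.0, 0.0],
                "luminance_level": 1,
                "config_tag": "B",
            }
        )
        ep = simulate_tuned_responses(trials, pop, seed=0)
        assert np.allclose(ep.data[0], ep.data[1], atol=1e-12)

    def test_kernel_support(self):
        t = np.arange(-250.0, 501.0, 10.0)
        k = temporal_kernel(t, 80.0, 40.0)
        assert np.all(k[t < 80.0] == 0)
        assert np.all(k[t > 120.0] == 0)
        assert k.max() <= 1.0


class TestMixing:
    def test_identity_gain_zero_noise_preserves_sources(self):
        trials = generate_stimulus_stream(CONFIG_B, 10, seed=0)
        src = simulate_tuned_responses(
            trials, PopulationConfig(n_units=4, signal_class="SOURCE"), seed=1
        )
        model = MixingModel(np.eye(4), np.linspace(0, 1, 4))
        sens = mix_to_sensors(src, model)
        assert np.allclose(sens.data, src.data)
        assert (sens.channels["signal_class"] == "SENSOR").all()

    def test_single_source_linearity(self):
        trials = generate_stimulus_stream(CONFIG_B, 5, seed=0)
        src = simulate_tuned_responses(
            trials, PopulationConfig(n_units=1, signal_class="SOURCE"), seed=1
        )
        gain = np.array([[0.5, -2.0, 3.0]])
        sens = mix_to_sensors(src, MixingModel(gain, [0.0]))
        for c, g in enumerate(gain[0]):
            assert np.allclose(sens.data[:, c], g * src.data[:, 0])

    def test_noiseless_sensor_rank_bounded_by_sources(self):
        trials = generate_stimulus_stream(CONFIG_B, 30, seed=0)
        src = simulate_tuned_responses(
            trials, PopulationConfig(n_units=3, signal_class="SOURCE"), seed=1
        )
        gain = np.random.default_rng(0).normal(size=(3, 10))
        sens = mix_to_sensors(src, MixingModel(gain, np.arange(3)))
        flat = sens.data.transpose(1, 0, 2).reshape(10, -1)
        assert np.linalg.matrix_rank(flat, tol=1e-8) <= 3

    def test_dimension_mismatch_rejected(self):
        trials = generate_stimulus_stream(CONFIG_B, 3, seed=0)
        src = simulate_tuned_responses(trials, PopulationConfig(n_units=4), seed=1)
        with pytest.raises(ValueError):
            mix_to_sensors(src, MixingModel(np.eye(3), np.arange(3)))

    def test_all_zero_source_row_rejected(self):
        gain = np.eye(3)
        gain[1] = 0.0
        with pytest.raises(ValueError):
            MixingModel(gain, np.arange(3))


class TestEyeTraces:
    def test_equiluminant_probe_zero_condition_difference(self):
        tr = generate_eye_traces([54.0, 55.0, 56.0], L_eq=55.0, noise_sd=0.0, seed=0)
        at = tr.probe_L == 55.0
        c1 = tr.positions[at & (tr.condition == 1)]
        c2 = tr.positions[at & (tr.condition == 2)]
        assert np.allclose(c1, c2)

    def test_condition_difference_flips_sign_across_L_eq(self):
        tr = generate_eye_traces([50.0, 60.0], L_eq=55.0, noise_sd=0.0, seed=0)

        def cond_diff(L):
            sel1 = (tr.probe_L == L) & (tr.condition == 1)
            sel2 = (tr.probe_L == L) & (tr.condition == 2)
            return tr.positions[sel1, -1].mean() - tr.positions[sel2, -1].mean()

        assert cond_diff(50.0) < 0 < cond_diff(60.0)

    def test_default_probe_grid_has_19_levels(self):
        tr = generate_eye_traces(seed=0)
        assert np.unique(tr.probe_L).size == 19

    def test_seed_determinism(self):
        a = generate_eye_traces(seed=4)
        b = generate_eye_traces(seed=4)
        assert np.array_equal(a.positions, b.positions)
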