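"""Generator contracts: determinism, parameter recovery, invariants."""

import numpy as np
import pytest

from pcphys import (BlinkGenSpec, EyeGenSpec, GroupSpec, SpecificationError,
                    SpikeGenSpec, fit_sine, gen_blink_session,
                    gen_excitability_cell, gen_eye_trial, gen_group_dataset,
                    gen_spiketrain, io_curve, isi_stats, t_from_raw)


class TestSpikeGenerator:
    def test_bit_identical_on_repeat(self):
        spec = SpikeGenSpec(modulation_type="oscillation", duration=30.0,
                            seed=9)
        a, b = gen_spiketrain(spec), gen_spiketrain(spec)
        assert np.array_equal(a.simple_spike_times, b.simple_spike_times)
        assert np.array_equal(a.complex_spike_times, b.complex_spike_times)

    def test_rate_recovered_within_three_renewal_ses(self):
        # SE of a renewal-process rate estimate: rate*CV/sqrt(n)
        spec = SpikeGenSpec(target_rate=60.0, target_cv=0.5, cs_rate=1.0,
                            cf_pause=15.0, duration=100.0, seed=1)
        tr = gen_spiketrain(spec)
        st = isi_stats(tr.simple_spike_times, tr.duration)
        se = 60.0 * 0.5 / np.sqrt(st.n_spikes)
        # the 1 Hz CS train deletes ~rate*cs_rate*pause spikes/s
        expected = 60.0 * (1.0 - 1.0 * 0.015)
        assert abs(st.rate - expected) < 3 * se

    def test_near_zero_cv_limit_is_metronomic(self):
        spec = SpikeGenSpec(target_rate=60.0, target_cv=1e-3, cs_rate=0.0,
                            duration=60.0, seed=2)
        st = isi_stats(gen_spiketrain(spec).simple_spike_times, 60.0)
        assert st.cv < 0.01

    def test_rate_and_cv_converge_to_targets_at_long_duration(self):
        spec = SpikeGenSpec(target_rate=60.0, target_cv=0.5, cs_rate=0.0,
                            duration=300.0, seed=3)
        st = isi_stats(gen_spiketrain(spec).simple_spike_times, 300.0)
        n = st.n_spikes
        assert abs(st.rate - 60.0) < 3 * 60.0 * 0.5 / np.sqrt(n)
        # CV estimator SE ~ cv*sqrt((1+2cv^2)/(2n)); generous 3x band
        assert abs(st.cv - 0.5) < 3 * 0.5 * np.sqrt((1 + 2 * 0.25) / (2 * n))

    @pytest.mark.parametrize("mod", ["normal", "facilitation", "suppression",
                                     "oscillation"])
    def test_pause_enforced_for_every_complex_spike(self, mod):
        spec = SpikeGenSpec(cf_pause=15.0, modulation_type=mod, duration=60.0,
                            seed=4)
        tr = gen_spiketrain(spec)
        idx = np.searchsorted(tr.simple_spike_times, tr.complex_spike_times)
        ok = idx < tr.simple_spike_times.size
        latencies = tr.simple_spike_times[idx[ok]] - tr.complex_spike_times[ok]
        assert latencies.min() >= 0.015

    def test_event_lists_are_disjoint_sorted_and_bounded(self):
        spec = SpikeGenSpec(modulation_type="facilitation", duration=60.0,
                            seed=5)
        tr = gen_spiketrain(spec)
        assert np.all(np.diff(tr.simple_spike_times) > 0)
        assert 0 <= tr.simple_spike_times[0]
        assert tr.simple_spike_times[-1] <= 60.0
        assert not np.intersect1d(tr.simple_spike_times,
                                  tr.complex_spike_times).size

    @pytest.mark.parametrize("fieldname,kwargs", [
        ("target_rate", {"target_rate": -5.0}),
        ("target_cv", {"target_cv": 0.0}),
        ("cs_rate", {"cs_rate": -1.0}),
        ("duration", {"duration": 0.0}),
        ("modulation_type", {"modulation_type": "bogus"}),
        ("oscillation_freq", {"modulation_type": "oscillation",
                              "oscillation_freq": 0.0}),
    ])
    def test_invalid_spec_names_the_field(self, fieldname, kwargs):
        with pytest.raises(SpecificationError, match=fieldname):
            gen_spiketrain(SpikeGenSpec(**kwargs))


class TestEyeGenerator:
    def test_identity_case_eye_equals_stimulus(self):
        spec = EyeGenSpec(true_gain=1.0, true_phase=0.0, noise_sd=0.0,
                          saccade_rate=0.0, condition="OKR", seed=0)
        tr = gen_eye_trial(spec)
        assert np.allclose(tr.eye_position, tr.stimulus_position, atol=1e-12)

    def test_zero_gain_leaves_no_component_at_stim_freq(self):
        spec = EyeGenSpec(true_gain=0.0, noise_sd=0.2, seed=1)
        tr = gen_eye_trial(spec)
        fit = fit_sine(tr.eye_position, tr.time, tr.stim_freq)
        assert fit.amplitude < 0.05  # noise floor only

    def test_noiseless_amplitude_recovered_exactly(self):
        spec = EyeGenSpec(true_gain=0.7, true_phase=12.0, noise_sd=0.0,
                          condition="OKR", seed=0)
        tr = gen_eye_trial(spec)
        fit = fit_sine(tr.eye_position, tr.time, tr.stim_freq)
        assert fit.amplitude == pytest.approx(0.7 * 5.0, abs=1e-9)
        assert fit.phase_deg == pytest.approx(12.0, abs=1e-6)

    def test_determinism(self):
        spec = EyeGenSpec(noise_sd=0.3, saccade_rate=0.2, seed=11)
        assert np.array_equal(gen_eye_trial(spec).eye_position,
                              gen_eye_trial(spec).eye_position)

    def test_invalid_phase_rejected(self):
        with pytest.raises(SpecificationError, match="true_phase"):
            gen_eye_trial(EyeGenSpec(true_phase=200.0))


class TestBlinkGenerator:
    def test_session_composition_and_order_determinism(self):
        spec = BlinkGenSpec(n_paired=10, n_cs_only=4, n_us_only=3, seed=2)
        a = gen_blink_session(spec)
        b = gen_blink_session(spec)
        assert [t.trial_type for t in a] == [t.trial_type for t in b]
        assert sorted(t.trial_type for t in a) == (
            ["cs_only"] * 4 + ["paired"] * 10 + ["us_only"] * 3)
        assert all(np.array_equal(x.trace, y.trace) for x, y in zip(a, b))

    def test_us_only_trials_reach_full_blink_amplitude(self):
        spec = BlinkGenSpec(n_paired=0, n_cs_only=0, n_us_only=5,
                            ur_amplitude=2.0, baseline_noise_sd=0.005, seed=3)
        for t in gen_blink_session(spec):
            assert t.trace.max() == pytest.approx(2.0, abs=0.1)

    def test_cs_only_without_cr_probability_stays_at_baseline(self):
        spec = BlinkGenSpec(n_paired=0, n_cs_only=10, n_us_only=0,
                            cr_probability=0.0, baseline_noise_sd=0.01, seed=4)
        for t in gen_blink_session(spec):
            assert np.abs(t.trace).max() < 0.06

    def test_invalid_fraction_draws_pre_cs_artifacts(self):
        spec = BlinkGenSpec(n_paired=100, n_cs_only=0, n_us_only=0,
                            invalid_fraction=0.1, seed=5)
        n_art = sum(np.abs(t.pre_cs_samples()).max()
                    > 10 * spec.baseline_noise_sd
                    for t in gen_blink_session(spec))
        # binomial(100, 0.1): 3-sigma band
        assert abs(n_art - 10) <= 3 * np.sqrt(100 * 0.1 * 0.9)

    def test_invalid_fraction_bounds_checked(self):
        with pytest.raises(SpecificationError, match="invalid_fraction"):
            gen_blink_session(BlinkGenSpec(invalid_fraction=1.5))


class TestExcitabilityGenerator:
    def test_noiseless_ladder_is_exact(self):
        sweeps = gen_excitability_cell(rheobase=100.0, slope=10.0)
        rates = [s.rate for s in sweeps]
        assert rates[:3] == [0.0, 0.0, 0.0]  # -100, 0, 100 pA
        assert rates[3:] == pytest.approx(list(np.arange(10.0, 101.0, 10.0)))

    def test_zero_slope_gives_silent_cell(self):
        sweeps = gen_excitability_cell(rheobase=0.0, slope=0.0)
        assert all(s.spike_count == 0 for s in sweeps)

    def test_slope_recovery_over_twenty_seeds(self):
        # printed loss-of-function excitability slope: 16.0 Hz/100 pA
        slopes = [io_curve(gen_excitability_cell(rheobase=100.0, slope=16.0,
                                                 noise_sd=1.0, seed=s)).slope
                  for s in range(20)]
        assert np.mean(slopes) == pytest.approx(16.0, abs=0.5)


class TestGroupDataset:
    def test_labels_sizes_and_positive_rates(self):
        groups = [GroupSpec("a", 50.0, 10.0, 3, duration=20.0),
                  GroupSpec("b", 40.0, 10.0, 4, duration=20.0)]
        trains = gen_group_dataset(groups, seed=0)
        assert sum(t.group == "a" for t in trains) == 3
        assert sum(t.group == "b" for t in trains) == 4
        for t in trains:
            assert isi_stats(t.simple_spike_times, t.duration).rate > 1.0

    def test_single_cell_group_rejected(self):
        with pytest.raises(SpecificationError):
            gen_group_dataset([GroupSpec("a", 50.0, 10.0, 1)], seed=0)

    def test_identical_groups_give_small_t(self):
        groups = [GroupSpec("a", 60.0, 5.0, 6, duration=30.0),
                  GroupSpec("b", 60.0, 5.0, 6, duration=30.0)]
        trains = gen_group_dataset(groups, seed=1)
        rates = {g: [isi_stats(t.simple_spike_times, t.duration).rate
                     for t in trains if t.group == g] for g in ("a", "b")}
        res = t_from_raw(rates["a"], rates["b"])
        assert abs(res.t) < 4.0  # null comparison
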