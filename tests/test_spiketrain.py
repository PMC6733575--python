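"""Spike-train statistics: ISI measures, CF pause, peri-CS profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcphys import (ContractError, InsufficientDataError, SpikeGenSpec,
                    SpikeTrain, cf_pause, classify_response, cs_stats,
                    gen_spiketrain, isi_stats, peri_cs_profile,
                    validate_single_unit)

# ---------------------------------------------------------------------------
# isi_stats


class TestISIStats:
    def test_perfectly_regular_train_has_zero_cv_and_cv2(self):
        t = np.arange(0, 1.0, 0.010)
        st_ = isi_stats(t, duration=1.0)
        assert st_.cv == pytest.approx(0.0, abs=1e-12)
        assert st_.mean_cv2 == pytest.approx(0.0, abs=1e-12)
        assert st_.rate == pytest.approx(100.0)

    def test_cv2_formula_on_two_isi_example(self):
        # ISIs 10 and 30 ms: CV2 = 2*|30-10| / (30+10) = 1.0
        st_ = isi_stats(np.array([0.0, 0.010, 0.040]), duration=0.05)
        assert st_.mean_cv2 == pytest.approx(1.0)
        assert st_.n_isi == st_.n_spikes - 1

    def test_exponential_isis_give_unit_cv_and_cv2(self, rng):
        # Poisson train: CV = 1 exactly; E[CV2] = 1 (adjacent-ISI ratio
        # is Beta(1,1)-flat), checked to Monte-Carlo accuracy at 1e6 ISIs
        isi = rng.exponential(0.01, size=1_000_000)
        t = np.cumsum(isi)
        st_ = isi_stats(t, duration=t[-1] + 0.01)
        assert st_.cv == pytest.approx(1.0, abs=0.01)
        assert st_.mean_cv2 == pytest.approx(1.0, abs=0.01)

    def test_gamma_renewal_cv_matches_inverse_sqrt_shape(self, rng):
        for k in (4.0, 16.0):
            isi = rng.gamma(k, 1.0 / k / 60.0, size=200_000)
            t = np.cumsum(isi)
            st_ = isi_stats(t, duration=float(t[-1]))
            assert st_.cv == pytest.approx(1.0 / np.sqrt(k), rel=0.02)

    def test_fewer_than_three_spikes_flags_cv_undefined(self):
        st_ = isi_stats(np.array([0.1, 0.2]), duration=1.0)
        assert st_.rate == pytest.approx(2.0)
        assert np.isnan(st_.cv) and np.isnan(st_.mean_cv2)

    def test_unsorted_input_is_a_contract_violation(self):
        with pytest.raises(ContractError):
            isi_stats(np.array([0.2, 0.1, 0.3]), duration=1.0)

    @given(st.lists(st.floats(1e-4, 10.0), min_size=3, max_size=60),
           st.floats(0.0, 100.0))
    def test_cv2_bounded_and_shift_invariant(self, isis, shift):
        t = np.cumsum(np.asarray(isis))
        a = isi_stats(t, duration=float(t[-1]) + 1.0)
        b = isi_stats(t + shift, duration=float(t[-1]) + shift + 1.0)
        assert 0.0 <= a.mean_cv2 <= 2.0
        assert a.cv == pytest.approx(b.cv, rel=1e-9, abs=1e-12)
        assert a.mean_cv2 == pytest.approx(b.mean_cv2, rel=1e-9, abs=1e-12)


class TestCSStats:
    def test_metronomic_cs_train(self, regular_train):
        st_ = cs_stats(regular_train)
        assert st_.rate == pytest.approx(1.0)  # 10 CSs in 10 s
        assert st_.cv == pytest.approx(0.0, abs=1e-12)

    def test_cs_rate_recovery_from_generator(self):
        spec = SpikeGenSpec(target_rate=60.0, cs_rate=1.2, duration=600.0,
                            seed=7)
        st_ = cs_stats(gen_spiketrain(spec))
        # Poisson CS process: SE = sqrt(rate/duration)
        assert st_.rate == pytest.approx(1.2, abs=3 * np.sqrt(1.2 / 600))


# ---------------------------------------------------------------------------
# CF pause / single unit


class TestCFPause:
    def test_single_pause_measured_exactly(self):
        tr = SpikeTrain(simple_spike_times=np.array([0.5, 1.015, 1.050]),
                        complex_spike_times=np.array([1.0]), duration=2.0)
        res = cf_pause(tr)
        assert res.mean_pause == pytest.approx(15.0)
        assert res.n_cs_used == 1

    def test_trailing_cs_without_following_ss_is_excluded(self):
        tr = SpikeTrain(simple_spike_times=np.array([0.5, 1.02]),
                        complex_spike_times=np.array([1.0, 1.5]), duration=2.0)
        res = cf_pause(tr)
        assert res.n_cs_used == 1

    def test_no_usable_cs_raises(self):
        tr = SpikeTrain(simple_spike_times=np.array([0.1]),
                        complex_spike_times=np.array([0.5]), duration=1.0)
        with pytest.raises(InsufficientDataError):
            cf_pause(tr)

    def test_poisson_train_pause_is_enforced_pause_plus_mean_isi(self):
        # after the enforced pause the memoryless (cv=1) process restarts:
        # E[pause] = p + 1/rate = 15 + 16.67 ms
        means = []
        for seed in range(5):
            spec = SpikeGenSpec(target_rate=60.0, target_cv=1.0, cs_rate=1.0,
                                cf_pause=15.0, duration=200.0, seed=seed)
            means.append(cf_pause(gen_spiketrain(spec)).mean_pause)
        assert np.mean(means) == pytest.approx(15.0 + 1000.0 / 60.0, abs=2.0)


class TestSingleUnit:
    def test_generator_pause_satisfies_weaker_criterion(self):
        spec = SpikeGenSpec(cf_pause=15.0, duration=60.0, seed=0)
        rep = validate_single_unit(gen_spiketrain(spec), min_pause=8.0)
        assert rep.status is True

    def test_contaminated_recording_is_flagged_with_the_cs(self):
        tr = SpikeTrain(simple_spike_times=np.array([0.5, 1.002, 2.02]),
                        complex_spike_times=np.array([1.0, 2.0]), duration=3.0)
        rep = validate_single_unit(tr, min_pause=8.0)
        assert rep.status is False
        assert list(rep.violating_cs_times) == [1.0]

    def test_no_complex_spikes_is_indeterminate(self):
        tr = SpikeTrain(simple_spike_times=np.array([0.1, 0.2, 0.3]),
                        complex_spike_times=np.array([]), duration=1.0)
        assert validate_single_unit(tr).status is None


# ---------------------------------------------------------------------------
# peri-CS profile and classification


class TestPeriCSProfile:
    def test_count_conservation_against_direct_recount(self):
        spec = SpikeGenSpec(duration=120.0, seed=3)
        tr = gen_spiketrain(spec)
        prof = peri_cs_profile(tr)
        total = 0
        for c in tr.complex_spike_times:
            rel = tr.simple_spike_times - c
            total += int(np.sum((rel >= -0.100) & (rel < 0.300)))
        assert prof.counts.sum() == total

    def test_too_few_complex_spikes_raises(self):
        tr = SpikeTrain(simple_spike_times=np.arange(0.0, 10.0, 0.02),
                        complex_spike_times=np.array([5.0001]), duration=10.0)
        with pytest.raises(InsufficientDataError):
            peri_cs_profile(tr)

    def test_bin_width_must_divide_window(self, regular_train):
        with pytest.raises(ContractError):
            peri_cs_profile(regular_train, bin_width=7.0, min_cs=5)

    def test_normal_train_has_no_systematic_modulation(self):
        spec = SpikeGenSpec(modulation_type="normal", duration=300.0, seed=11)
        prof = peri_cs_profile(gen_spiketrain(spec))
        post = prof.bin_edges[:-1] >= 30.0  # clear of the pause
        assert np.nanmean(np.abs(prof.z_per_bin[post])) < 2.0

    def test_suppression_train_shows_sub_baseline_bins(self):
        spec = SpikeGenSpec(modulation_type="suppression", duration=300.0,
                            seed=5)
        prof = peri_cs_profile(gen_spiketrain(spec))
        window = (prof.bin_edges[:-1] >= 30.0) & (prof.bin_edges[1:] <= 100.0)
        assert np.nanmin(prof.z_per_bin[window]) < -2.0


class TestClassification:
    @pytest.mark.parametrize("mod", ["normal", "facilitation", "suppression",
                                     "oscillation"])
    def test_each_generator_type_is_recovered(self, mod):
        spec = SpikeGenSpec(modulation_type=mod, duration=300.0, seed=42)
        label = classify_response(peri_cs_profile(gen_spiketrain(spec)))
        assert label == mod

    def test_low_rate_regular_oscillator_is_detected(self):
        # oscillations are seen in cells firing < 50 Hz with CV < 0.3
        spec = SpikeGenSpec(target_rate=40.0, target_cv=0.2,
                            modulation_type="oscillation", duration=300.0,
                            seed=1)
        label = classify_response(peri_cs_profile(gen_spiketrain(spec)))
        assert label == "oscillation"

    def test_undefined_baseline_raises(self, regular_train):
        prof = peri_cs_profile(regular_train, min_cs=5)
        prof.baseline_rate = 0.0
        with pytest.raises(InsufficientDataError):
            classify_response(prof)
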