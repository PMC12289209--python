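"""Activity labelling, glide extraction, FFT classification, time budgets."""

import numpy as np
import pytest

import squidtag as st
from squidtag.gait import ACTIVE_WINDOW_S, SpectralConfig
from squidtag.synthetic import FAST_HZ

from conftest import balanced_script


def train_at(times):
    times = np.asarray(times, float)
    return st.FinEventTrain(times, np.ones_like(times), np.full_like(times, 0.5))


def const_surge(n_seconds, level=0.0):
    return np.full(n_seconds * FAST_HZ, level)


class TestExtractDynamicSurge:
    def test_static_component_removed(self):
        surge = st.extract_dynamic_surge(np.full(2000, 1.0))
        assert np.allclose(surge, 0.0, atol=1e-12)

    def test_sinusoid_amplitude_preserved(self):
        # 2 Hz, amplitude 0.15 g over a 1 g postural offset: the 0.5 s
        # running mean spans exactly one period, so the oscillation passes
        # through untouched (analytic filter response)
        t = np.arange(3000) / FAST_HZ
        a = 1.0 + 0.15 * np.sin(2 * np.pi * 2.0 * t)
        surge = st.extract_dynamic_surge(a)
        assert np.abs(surge[200:-200]).max() == pytest.approx(0.15, abs=0.01)

    def test_jet_pulses_cross_threshold(self):
        rec, _ = st.simulate_recording(
            st.BehaviourScript(
                (st.ScriptEntry("jet", 30.0, st.GaitParams(jet_surge_peak=0.2)),),
                seed=4,
            )
        )
        surge = st.extract_dynamic_surge(rec.accel_xyz)
        m = np.abs(surge[: 30 * FAST_HZ]).reshape(30, FAST_HZ).max(axis=1)
        assert (m > 0.10).any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.extract_dynamic_surge(np.empty(0))


class TestLabelWindows:
    def test_fin_event_makes_active(self):
        w = st.label_windows(train_at([0.5]), const_surge(1, 0.02))
        assert w[0].label == "active" and w[0].has_fin_event

    def test_surge_above_threshold_makes_active(self):
        surge = const_surge(1, 0.0)
        surge[50] = 0.12
        w = st.label_windows(train_at([]), surge)
        assert w[0].label == "active"

    def test_neither_condition_inactive(self):
        surge = const_surge(1, 0.0)
        surge[50] = 0.05
        w = st.label_windows(train_at([]), surge)
        assert w[0].label == "inactive"

    def test_threshold_uses_absolute_surge(self):
        surge = const_surge(1, 0.0)
        surge[50] = -0.12
        w = st.label_windows(train_at([]), surge)
        assert w[0].label == "active"


class TestSegmentStates:
    def windows(self, labels):
        return [
            st.ActivityWindow(float(i), lab == "A", 0.15 if lab == "A" else 0.02,
                              "active" if lab == "A" else "inactive")
            for i, lab in enumerate(labels)
        ]

    def test_short_inactive_not_glide(self):
        segs, active = st.segment_states(
            self.windows("AAIIIIAA"), short_inactive="unclassified"
        )
        states = [s.state for s in segs]
        assert "glide" not in states and "unclassified" in states

    def test_long_inactive_becomes_single_glide(self):
        segs, _ = st.segment_states(self.windows("A" + "I" * 157 + "A"))
        glides = [s for s in segs if s.state == "glide"]
        assert len(glides) == 1
        assert glides[0].duration == pytest.approx(157.0)

    def test_alternating_windows_no_glides(self):
        segs, active = st.segment_states(self.windows("AIAIAIAIAI"))
        assert not any(s.state == "glide" for s in segs)

    def test_merge_absorbs_short_inactive(self):
        _, active = st.segment_states(self.windows("AAIIAA"))
        assert active == [(0.0, 6.0)]

    def test_unclassified_mode_splits_runs(self):
        segs, active = st.segment_states(
            self.windows("AAIIAA"), short_inactive="unclassified"
        )
        assert active == [(0.0, 2.0), (4.0, 6.0)]
        assert [s.state for s in segs] == ["unclassified"]

    def test_noncontiguous_rejected(self):
        w = self.windows("AAA")
        w[2] = st.ActivityWindow(7.0, True, 0.2, "active")
        with pytest.raises(ValueError):
            st.segment_states(w)


class TestDominantFrequency:
    cfg = SpectralConfig()

    @pytest.mark.parametrize("freq", [0.4, 0.7, 1.12, 1.5, 2.0])
    def test_resolution_bound(self, freq):
        """Error bounded by fs/(window+pad) ~ 0.0095 Hz for pure tones with
        at least two cycles in the window, at any phase."""
        t = np.arange(self.cfg.n_window) / self.cfg.sample_rate
        for phase in np.linspace(0, np.pi, 5):
            x = 3.0 + np.sin(2 * np.pi * freq * t + phase)
            assert st.dominant_frequency(x, self.cfg) == pytest.approx(
                freq, abs=self.cfg.resolution
            )

    @pytest.mark.parametrize("freq", [0.2, 0.25, 0.3])
    def test_single_cycle_bias_bounded(self, freq):
        """Below ~2 cycles per window the negative-frequency image of the
        Hann main lobe biases the magnitude peak; the bias stays under
        0.08 Hz and vanishes by 0.4 Hz."""
        t = np.arange(self.cfg.n_window) / self.cfg.sample_rate
        for phase in np.linspace(0, np.pi, 5):
            x = 3.0 + np.sin(2 * np.pi * freq * t + phase)
            assert st.dominant_frequency(x, self.cfg) == pytest.approx(
                freq, abs=0.08
            )

    def test_constant_segment_errors(self):
        with pytest.raises(ValueError):
            st.dominant_frequency(np.full(self.cfg.n_window, 2.0), self.cfg)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            st.dominant_frequency(np.zeros(100), self.cfg)

    def test_resolution_value(self):
        assert self.cfg.resolution == pytest.approx(100 / 10500)


class TestFindSplitFrequency:
    def test_bimodal_mixture_split_between_modes(self):
        rng = np.random.default_rng(0)
        freqs = np.concatenate([
            rng.normal(1.1, 0.05, 120), rng.normal(0.4, 0.05, 80)
        ])
        split = st.find_split_frequency(freqs)
        assert 0.55 < split < 0.95

    def test_unimodal_falls_back_with_warning(self):
        rng = np.random.default_rng(1)
        freqs = rng.normal(1.1, 0.05, 200)
        with pytest.warns(RuntimeWarning):
            split = st.find_split_frequency(freqs, fallback=0.75)
        assert split == 0.75

    def test_two_tight_modes(self):
        rng = np.random.default_rng(2)
        freqs = np.concatenate([
            rng.normal(0.4, 0.004, 60), rng.normal(1.2, 0.004, 60)
        ])
        split = st.find_split_frequency(freqs)
        assert 0.4 < split < 1.2

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            st.find_split_frequency(np.ones(10))


class TestClassifyActiveWindows:
    def synth_inputs(self, fin_freq, surge_peak, duration=10.0):
        t = np.arange(int(duration * FAST_HZ)) / FAST_HZ
        sig = st.ConditionedSignal(t, 5 + np.sin(2 * np.pi * fin_freq * t))
        surge = np.zeros_like(t)
        surge[::100] = surge_peak
        return sig, surge

    def test_high_freq_low_surge_is_finning(self):
        sig, surge = self.synth_inputs(1.1, 0.05)
        segs = st.classify_active_windows([(0.0, 10.0)], sig, surge, split=0.7)
        assert all(s.state == "finning" and not s.jet_overlap_flag for s in segs)

    def test_low_freq_high_surge_is_jet(self):
        sig, surge = self.synth_inputs(0.45, 0.18)
        segs = st.classify_active_windows([(0.0, 10.0)], sig, surge, split=0.7)
        assert all(s.state == "jet" for s in segs)

    def test_low_freq_low_surge_is_other(self):
        sig, surge = self.synth_inputs(0.45, 0.05)
        segs = st.classify_active_windows([(0.0, 10.0)], sig, surge, split=0.7)
        assert all(s.state == "other" for s in segs)

    def test_finning_with_surge_sets_overlap_flag(self):
        sig, surge = self.synth_inputs(1.1, 0.15)
        segs = st.classify_active_windows([(0.0, 10.0)], sig, surge, split=0.7)
        assert all(s.state == "finning" and s.jet_overlap_flag for s in segs)

    def test_trailing_remainder_unclassified(self):
        sig, surge = self.synth_inputs(1.1, 0.05, duration=13.0)
        segs = st.classify_active_windows([(0.0, 13.0)], sig, surge, split=0.7)
        assert segs[-1].state == "unclassified"
        assert segs[-1].duration == pytest.approx(3.0)

    def test_invalid_split_rejected(self):
        sig, surge = self.synth_inputs(1.1, 0.05)
        with pytest.raises(ValueError):
            st.classify_active_windows([(0.0, 10.0)], sig, surge, split=0.0)


class TestComputeTimeBudget:
    def test_fractions_sum_to_one(self, mixed_recording):
        rec, truth = mixed_recording
        segs = [st.GaitSegment(a, b, s) for a, b, s in truth.state_intervals]
        budget = st.compute_time_budget(
            segs, train_at(truth.fin_event_times)
        )
        assert sum(budget.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_glide_fraction_one(self):
        budget = st.compute_time_budget(
            [st.GaitSegment(0.0, 100.0, "glide")], train_at([])
        )
        assert budget.fractions["glide"] == pytest.approx(1.0)

    def test_mean_fin_rate_from_ground_truth(self):
        # 1.0 Hz scripted finning: events / finning time = 1.0 +- 0.05
        segs = [st.GaitSegment(0.0, 120.0, "finning")]
        events = np.arange(0.25, 120.0, 1.0)
        budget = st.compute_time_budget(segs, train_at(events))
        assert budget.mean_fin_rate == pytest.approx(1.0, abs=0.05)

    def test_overlapping_segments_rejected(self):
        segs = [st.GaitSegment(0.0, 10.0, "finning"),
                st.GaitSegment(5.0, 15.0, "glide")]
        with pytest.raises(ValueError):
            st.compute_time_budget(segs, train_at([]))

    def test_surge_threshold_monotonicity(self):
        """Raising the surge threshold never increases the jet fraction."""
        rec, truth = st.simulate_recording(balanced_script(seed=13))
        sig = st.condition_signal(rec.mag_xyz)
        surge = st.extract_dynamic_surge(rec.accel_xyz)
        train = st.filter_isolated_peaks(
            st.detect_peaks(sig, st.PeakParams(0.4, 0.1, 2.5))
        )
        jet_fracs = []
        for thr in (0.05, 0.10, 0.15, 0.25):
            windows = st.label_windows(train, surge, thr)
            segs, active = st.segment_states(windows)
            segs = segs + st.classify_active_windows(active, sig, surge, 0.75, thr)
            budget = st.compute_time_budget(segs, train)
            jet_fracs.append(budget.fractions["jet"])
        assert all(a >= b for a, b in zip(jet_fracs, jet_fracs[1:]))

    def test_min_glide_monotonicity(self):
        """Raising min_glide never increases the glide fraction."""
        rec, truth = st.simulate_recording(balanced_script(seed=14))
        sig = st.condition_signal(rec.mag_xyz)
        surge = st.extract_dynamic_surge(rec.accel_xyz)
        train = st.filter_isolated_peaks(
            st.detect_peaks(sig, st.PeakParams(0.4, 0.1, 2.5))
        )
        windows = st.label_windows(train, surge)
        fracs = []
        for mg in (3, 5, 10, 30):
            segs, active = st.segment_states(windows, min_glide=mg)
            total = sum(s.duration for s in segs) + sum(b - a for a, b in active)
            glide = sum(s.duration for s in segs if s.state == "glide")
            fracs.append(glide / total)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
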