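"""Session containers, binning, trial selection and unit classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbgtimer.core import (
    LICK_TIME_RANGES,
    PerturbationSpec,
    Session,
    Trial,
    Unit,
    bin_spikes,
    classify_unit,
    group_trials_by_lick_time,
    select_engaged_trials,
)
from tests.conftest import make_trials


class TestTypes:
    def test_perturbation_invariants(self):
        with pytest.raises(ValueError):
            PerturbationSpec(target="ALM", duration=0.0)
        with pytest.raises(ValueError):
            PerturbationSpec(target="ALM", duration=0.6, ramp_down=0.7)
        assert PerturbationSpec(target="ALM").offset == pytest.approx(1.2)

    def test_rewarded_trial_needs_valid_lick(self):
        with pytest.raises(ValueError):
            Trial(index=0, delay_duration=1.0, rewarded=True)
        with pytest.raises(ValueError):
            Trial(index=0, delay_duration=1.0, first_lick_time=0.5, rewarded=True)

    def test_unit_spike_times_sorted(self):
        with pytest.raises(ValueError):
            Unit("u", "ALM", np.array([1.0, 0.5]))

    def test_session_trial_count_matches_onsets(self):
        trials = make_trials([1.0, 1.2])
        with pytest.raises(ValueError):
            Session("a", "s", trials, np.array([0.0]))


class TestBinSpikes:
    def test_rate_unit_conversion(self, tiny_session):
        # one spike per 50-ms bin = 20 spikes/s
        onset = 100.0
        st_times = onset + 0.025 + 0.05 * np.arange(20)
        sess = Session(
            "a", "s", make_trials([1.5]), np.array([onset]),
            units=[Unit("u", "ALM", st_times)],
        )
        t = bin_spikes(sess, 0.05, "cue", (0.0, 1.0))
        assert np.allclose(t.values[0, 0], 20.0)

    def test_count_conservation_unsmoothed(self, synth_session):
        session, _ = synth_session
        t = bin_spikes(session, 0.05, "cue", (-0.5, 1.0),
                       trial_indices=range(0, 20))
        total = t.values.sum(axis=2) * t.bin_size
        expected = np.zeros_like(total)
        for r, i in enumerate(t.trial_indices):
            onset = session.cue_onsets[i]
            for u, unit in enumerate(session.units):
                expected[r, u] = np.sum(
                    (unit.spike_times >= onset - 0.5) & (unit.spike_times < onset + 1.0)
                )
        assert np.allclose(total, expected)

    def test_causal_boxcar_is_identity_on_constant_rate(self):
        onset = 0.0
        st_times = 0.0005 + 0.001 * np.arange(1000)  # 1 spike/ms for 1 s
        sess = Session("a", "s", make_trials([1.5]), np.array([onset]),
                       units=[Unit("u", "ALM", st_times)])
        raw = bin_spikes(sess, 0.001, "cue", (0.0, 1.0))
        smooth = bin_spikes(sess, 0.001, "cue", (0.0, 1.0), smoothing=0.2)
        assert np.allclose(smooth.values, raw.values)

    def test_causal_boxcar_support(self):
        # single spike at 0.5 s with a 200-ms causal boxcar spreads only
        # forward in time: nonzero exactly in [0.5, 0.7)
        sess = Session("a", "s", make_trials([1.5]), np.array([0.0]),
                       units=[Unit("u", "ALM", np.array([0.5004]))])
        t = bin_spikes(sess, 0.001, "cue", (0.0, 1.0), smoothing=0.2)
        nz = np.nonzero(t.values[0, 0])[0]
        centers = t.bin_centers[nz]
        assert centers.min() >= 0.5
        assert centers.max() < 0.7

    def test_lick_alignment_drops_no_lick_trials(self, tiny_session):
        t = bin_spikes(tiny_session, 0.1, "lick", (-0.5, 0.2))
        assert list(t.trial_indices) == [0, 2]

    def test_empty_units_error(self):
        sess = Session("a", "s", make_trials([1.0]), np.array([0.0]), units=[])
        with pytest.raises(ValueError):
            bin_spikes(sess, 0.05)


class TestEngagedTrials:
    @staticmethod
    def _session(licks):
        trials = make_trials(licks)
        return Session("a", "s", trials, np.arange(len(licks), dtype=float))

    def test_all_licked_extends_to_last_trial(self):
        sess = self._session([1.0] * 50)
        assert select_engaged_trials(sess) == (4, 50)

    def test_no_lick_run_trims_twenty_trials(self):
        # licks from trial 1 (0-based), no-lick run at 100-102, none later
        licks = [np.nan] + [1.0] * 200
        for i in (100, 101, 102):
            licks[i] = np.nan
        sess = self._session(licks)
        start, stop = select_engaged_trials(sess)
        assert (start, stop - 1) == (5, 79)

    def test_too_few_lick_trials_is_empty(self):
        sess = self._session([1.0, 1.0, np.nan, 1.0, 1.0, np.nan])
        assert select_engaged_trials(sess) is None

    def test_perturbed_no_lick_runs_do_not_count(self):
        licks = [1.0] * 120
        for i in (60, 61, 62):
            licks[i] = np.nan
        perturbed = [False] * 120
        for i in (60, 61, 62):
            perturbed[i] = True
        trials = make_trials(licks, perturbed=perturbed)
        sess = Session("a", "s", trials, np.arange(120, dtype=float))
        assert select_engaged_trials(sess) == (4, 120)

    def test_invariant_to_trials_outside_range(self):
        licks = [np.nan] + [1.0] * 200
        for i in (100, 101, 102):
            licks[i] = np.nan
        sess = self._session(licks)
        rng_a = select_engaged_trials(sess)
        licks[150] = 0.4  # outside the engaged range
        sess2 = self._session(licks)
        assert select_engaged_trials(sess2) == rng_a


class TestClassifyUnit:
    @pytest.mark.parametrize(
        "area,kwargs,expected",
        [
            ("ALM", dict(mean_rate=3.0, spike_width=0.6), "ALM_pyramidal"),
            ("ALM", dict(mean_rate=3.0, spike_width=0.4), "ALM_other"),
            ("ALM", dict(mean_rate=0.3, spike_width=0.6), "ALM_other"),
            ("VLS", dict(mean_rate=2.0, spike_width=0.45, post_spike_suppression=30.0), "SPN"),
            ("VLS", dict(mean_rate=2.0, spike_width=0.3, long_isi_fraction=0.05), "FSI"),
            ("VLS", dict(mean_rate=2.0, spike_width=0.3, long_isi_fraction=0.5), "TAN"),
            ("VLS", dict(mean_rate=0.05, spike_width=0.45), "unclassified"),
        ],
    )
    def test_rule_application(self, area, kwargs, expected):
        unit = Unit("u", area, np.array([1.0]), **kwargs)
        assert classify_unit(unit) == expected

    def test_missing_features_warn_unclassified(self):
        unit = Unit("u", "ALM", np.array([1.0]))
        with pytest.warns(UserWarning):
            assert classify_unit(unit) == "unclassified"

    @given(
        rate=st.floats(0.0, 20.0),
        width=st.floats(0.1, 1.0),
        supp=st.floats(0.0, 100.0),
        isi=st.floats(0.0, 1.0),
        area=st.sampled_from(["ALM", "VLS"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_classification_is_a_partition(self, rate, width, supp, isi, area):
        unit = Unit("u", area, np.array([1.0]), mean_rate=rate, spike_width=width,
                    post_spike_suppression=supp, long_isi_fraction=isi)
        label = classify_unit(unit)
        assert label in {"ALM_pyramidal", "ALM_other", "SPN", "FSI", "TAN", "unclassified"}


class TestGroupTrials:
    def test_half_open_boundary(self):
        trials = make_trials([1.10])
        groups = group_trials_by_lick_time(trials)
        assert groups[(1.10, 1.25)] == [0]
        assert groups[(0.80, 1.10)] == []

    def test_no_lick_and_out_of_range_excluded(self):
        trials = make_trials([np.nan, 2.5])
        groups = group_trials_by_lick_time(trials)
        assert all(len(v) == 0 for v in groups.values())

    def test_overlap_raises(self):
        trials = make_trials([1.0])
        with pytest.raises(ValueError):
            group_trials_by_lick_time(trials, [(0.5, 1.2), (1.0, 1.5)])

    @given(st.lists(st.floats(0.2, 3.0), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_each_trial_in_at_most_one_group(self, licks):
        trials = make_trials(licks)
        groups = group_trials_by_lick_time(trials, LICK_TIME_RANGES)
        seen = [i for v in groups.values() for i in v]
        assert len(seen) == len(set(seen))
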