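"""Warping, across-trial variance, ramp fits, modulation tests, partial correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata

from cbgtimer.core import Session, Unit
from cbgtimer.single_cell import (
    across_trial_variance,
    characterize_ramp,
    partial_rank_correlation,
    photostim_modulation,
    prelick_modulation,
    warp_spike_times,
)
from cbgtimer.single_cell import _partial_spearman
from cbgtimer.synth import BehaviorGenConfig, NeuralGenConfig, make_session
from tests.conftest import make_trials


class TestWarping:
    def test_formula(self):
        assert warp_spike_times(np.array([0.7]), 1.4)[0] == pytest.approx(0.5)

    def test_identity_when_lick_equals_target(self):
        spikes = np.array([0.2, 0.9])
        assert np.allclose(warp_spike_times(spikes, 1.0), spikes)

    def test_endpoint_preserved(self):
        assert warp_spike_times(np.array([1.4]), 1.4)[0] == pytest.approx(1.0)

    def test_nonpositive_lick_rejected(self):
        with pytest.raises(ValueError):
            warp_spike_times(np.array([0.5]), 0.0)

    @given(st.lists(st.floats(0.001, 3.0), min_size=0, max_size=50),
           st.floats(0.3, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_count_preserved(self, spikes, lick):
        warped = warp_spike_times(np.array(spikes), lick)
        assert warped.size == len(spikes)


@pytest.fixture(scope="module")
def scalable_session():
    return make_session(
        behavior=BehaviorGenConfig(n_trials=1000),
        neural=NeuralGenConfig(n_units=10, scalable_fraction=0.5),
        seed=2,
    )


class TestVariance:
    def test_identical_trials_zero_variance(self):
        # same spike pattern and lick on every trial
        onsets = 10.0 * np.arange(20)
        spikes = np.sort(np.concatenate([onsets + 0.25, onsets + 0.75]))
        sess = Session("a", "s", make_trials([1.0] * 20), onsets,
                       units=[Unit("u", "ALM", spikes)])
        res = across_trial_variance(sess, 0, n_boot=50, seed=0)
        assert res.var_orig == pytest.approx(0.0)
        assert res.var_warped == pytest.approx(0.0)

    def test_scalable_units_reduce_absolute_units_do_not(self, scalable_session):
        session, truth = scalable_session
        flags = {"scalable": [], "absolute": []}
        for j in range(session.n_units):
            res = across_trial_variance(session, j, n_boot=300, seed=0)
            key = "scalable" if truth.unit_scalable[j] else "absolute"
            flags[key].append(res.significant_reduction)
        assert np.mean(flags["scalable"]) >= 0.5
        assert np.mean(flags["absolute"]) <= 0.15


class TestRampCharacterization:
    @staticmethod
    def _session_from_rate(rate_fn, n_trials=60, lick=1.3, seed=0):
        rng = np.random.default_rng(seed)
        onsets = 10.0 * np.arange(n_trials)
        spikes = []
        dt = 0.001
        t = dt * (np.arange(int(lick / dt)) + 0.5)
        lam = rate_fn(t) * dt
        for onset in onsets:
            counts = rng.poisson(lam)
            spikes.append(onset + np.repeat(t, counts))
        unit = Unit("u", "ALM", np.sort(np.concatenate(spikes)))
        return Session("a", "s", make_trials([lick] * n_trials), onsets, [unit])

    def test_linear_ramp_is_low_order_and_monotonic(self):
        sess = self._session_from_rate(lambda t: 40.0 * t + 2.0)
        fit = characterize_ramp(sess, 0, lick_range=(1.25, 1.5), seed=0)
        assert fit.order <= 2
        assert fit.monotonic
        assert fit.peak_time > 1.0  # peaks at the lick end

    def test_mid_trial_bump_detected(self):
        sess = self._session_from_rate(
            lambda t: 2.0 + 40.0 * np.exp(-((t - 0.6) ** 2) / (2 * 0.1**2))
        )
        fit = characterize_ramp(sess, 0, lick_range=(1.25, 1.5), seed=0)
        assert not fit.monotonic
        assert fit.peak_time == pytest.approx(0.6, abs=0.15)

    def test_too_few_trials_skipped(self):
        sess = self._session_from_rate(lambda t: 10.0 * t, n_trials=20)
        assert characterize_ramp(sess, 0, lick_range=(1.25, 1.5)) is None


class TestModulation:
    def test_prelick_rate_doubling_is_significant(self):
        rng = np.random.default_rng(0)
        onsets = 10.0 * np.arange(50)
        spikes = []
        for onset in onsets:
            base = onset - 1.0 + rng.uniform(0, 1, rng.poisson(8))
            pre = onset + 1.0 + rng.uniform(0, 0.3, rng.poisson(10))  # 0.2-0.5 before lick at 1.4
            spikes.extend([base, pre])
        unit = Unit("u", "ALM", np.sort(np.concatenate(spikes)))
        sess = Session("a", "s", make_trials([1.4] * 50), onsets, [unit])
        res = prelick_modulation(sess, 0)
        assert res.p_value < 0.01
        assert res.direction == "excited"

    def test_photostim_silenced_unit_classified_inhibited(self):
        cfg = BehaviorGenConfig(n_trials=400, perturb_fraction=0.2, perturb_kind="pause")
        session, _ = make_session(behavior=cfg, neural=NeuralGenConfig(n_units=4), seed=3)
        res = photostim_modulation(session, 0)
        assert res.direction == "inhibited"
        assert res.p_value < 0.01

    def test_photostim_test_calibrated_under_null(self):
        # no perturbation effect on rates -> rejection near the nominal level
        rng = np.random.default_rng(1)
        rejections = 0
        n_units = 120
        onsets = 8.0 * np.arange(60)
        trials = make_trials([2.0] * 60, perturbed=[i % 3 == 0 for i in range(60)])
        for _ in range(n_units):
            spikes = np.sort(np.concatenate(
                [o + rng.uniform(0, 2.0, rng.poisson(16)) for o in onsets]
            ))
            sess = Session("a", "s", trials, onsets, [Unit("u", "ALM", spikes)])
            res = photostim_modulation(sess, 0)
            rejections += res.p_value < 0.05
        assert rejections / n_units <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_units)


class TestPartialCorrelation:
    def test_reduces_to_plain_correlation_when_conditioner_independent(self, rng):
        n = 2000
        r = rng.normal(size=n)
        p = 0.5 * r + rng.normal(size=n)
        u = rng.normal(size=n)   # essentially uncorrelated with both at large n
        from scipy.stats import spearmanr
        rho_partial = _partial_spearman(r, p, u)
        rho_plain = spearmanr(r, p).statistic
        assert rho_partial == pytest.approx(rho_plain, abs=0.05)

    def test_identical_ranks_give_unity(self, rng):
        r = rng.normal(size=100)
        u = rng.normal(size=100)
        assert _partial_spearman(r, r.copy(), u) == pytest.approx(1.0, abs=1e-9)

    def test_matches_residual_rank_oracle(self, rng):
        # rank both variables, regress out the conditioner's ranks, correlate
        def oracle(r, p, u):
            rr, pp, uu = rankdata(r), rankdata(p), rankdata(u)
            Z = np.column_stack([np.ones_like(uu), uu])
            resid = lambda x: x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            return pearsonr(resid(rr), resid(pp)).statistic

        for _ in range(200):
            n = int(rng.integers(20, 80))
            r, p, u = rng.normal(size=(3, n))
            assert abs(_partial_spearman(r, p, u) - oracle(r, p, u)) < 1e-10

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            r, p, u = rng.normal(size=(3, 40))
            a = _partial_spearman(r, p, u)
            b = _partial_spearman(p, r, u)
            assert a == pytest.approx(b, abs=1e-12)
            assert -1.0 <= a <= 1.0

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            partial_rank_correlation(np.ones(30), rng.normal(size=30), rng.normal(size=30))

    def test_shuffle_null_flags_real_history_signal(self, rng):
        n = 300
        p = rng.normal(size=n)
        u = 0.5 * p + rng.normal(size=n)
        r = 0.8 * p + 0.3 * rng.normal(size=n)
        res = partial_rank_correlation(r, p, u, n_shuffles=300, seed=1)
        assert res.significant and res.rho > 0
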