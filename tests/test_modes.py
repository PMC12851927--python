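"""Population modes: definitions, projections, correlations, vector fields."""

import numpy as np
import pytest

from cbgtimer.core import Session, Unit, bin_spikes
from cbgtimer.modes import (
    assemble_pseudo_session,
    define_modes,
    define_trial_history_mode,
    mode_angle,
    population_correlation_analysis,
    project,
    variance_explained,
    vector_field_2d,
)
from cbgtimer.synth import BehaviorGenConfig, NeuralGenConfig, make_session
from tests.conftest import make_trials


@pytest.fixture(scope="module")
def mode_session():
    session, truth = make_session(
        behavior=BehaviorGenConfig(n_trials=250),
        neural=NeuralGenConfig(n_units=25),
        seed=7,
    )
    return session, truth


class TestDefineModes:
    def test_single_unit_ramp_mode_is_plus_one(self):
        # one unit firing more before the lick than before the cue
        onsets = 10.0 * np.arange(30)
        spikes = np.sort(np.concatenate([o + np.arange(0.9, 1.3, 0.02) for o in onsets]))
        sess = Session("a", "s", make_trials([1.3] * 30), onsets,
                       [Unit("u", "ALM", spikes)])
        ms = define_modes(sess, names=("ramp",))
        assert ms["ramp"][0] == pytest.approx(1.0)

    def test_orthogonalization_record(self, mode_session):
        session, _ = mode_session
        ms = define_modes(session)
        ms.check(tol=1e-10)
        assert abs(ms["middle"] @ ms["ramp"]) < 1e-10
        assert abs(ms["cue"] @ ms["ramp"]) < 1e-10
        assert abs(ms["cue"] @ ms["middle"]) < 1e-10
        assert abs(ms["execution"] @ ms["ramp"]) < 1e-10

    def test_unit_permutation_equivariance(self, mode_session):
        session, _ = mode_session
        ms = define_modes(session)
        perm = np.random.default_rng(0).permutation(session.n_units)
        permuted = Session(
            session.animal_id, session.session_id, session.trials,
            session.cue_onsets, [session.units[i] for i in perm],
        )
        ms2 = define_modes(permuted)
        assert np.allclose(ms2["ramp"], ms["ramp"][perm], atol=1e-12)


class TestTrialHistoryMode:
    def test_recovers_planted_history_coefficients(self):
        session, truth = make_session(
            behavior=BehaviorGenConfig(n_trials=200),
            neural=NeuralGenConfig(n_units=50, history_fraction=0.6),
            seed=11,
        )
        idx = np.array([i for i, t in enumerate(session.trials) if t.cue_present])
        tensor = bin_spikes(session, 0.1, "cue", (-1.0, 0.0), trial_indices=idx)
        iti = tensor.values.mean(axis=2)
        mode = define_trial_history_mode(iti, truth.mu[tensor.trial_indices])
        r = np.corrcoef(mode, truth.unit_history_coef)[0, 1]
        assert r > 0.8
        assert np.linalg.norm(mode) == pytest.approx(1.0)

    def test_shuffled_labels_destroy_loadings(self, mode_session, rng):
        session, truth = mode_session
        idx = np.array([i for i, t in enumerate(session.trials) if t.cue_present])
        tensor = bin_spikes(session, 0.1, "cue", (-1.0, 0.0), trial_indices=idx)
        iti = tensor.values.mean(axis=2)
        mode = define_trial_history_mode(iti, rng.permutation(truth.mu[tensor.trial_indices]))
        r = np.corrcoef(mode, truth.unit_history_coef)[0, 1]
        assert abs(r) < 0.45


class TestProjection:
    def test_inner_product_identity(self, rng):
        mode = rng.normal(size=12)
        mode /= np.linalg.norm(mode)
        activity = 3.0 * mode[:, None] * np.ones((1, 7))
        proj = project(activity[None], mode)
        assert np.allclose(proj, 3.0)

    def test_linearity(self, rng):
        mode = rng.normal(size=6)
        A, B = rng.normal(size=(2, 4, 6, 5))
        left = project(2.0 * A + 3.0 * B, mode)
        right = 2.0 * project(A, mode) + 3.0 * project(B, mode)
        assert np.allclose(left, right)

    def test_zero_activity_zero_projection_without_mean_subtraction(self, rng):
        mode = rng.normal(size=5)
        proj = project(np.zeros((2, 5, 4)), mode, normalization="control_sd",
                       control_sd=1.0)
        assert np.all(proj == 0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            project(np.zeros((2, 5, 4)), np.ones(6))


class TestVarianceExplained:
    def test_single_direction_takes_all_power(self, rng):
        w = rng.normal(size=8)
        w /= np.linalg.norm(w)
        activity = w[:, None] * rng.normal(size=10)
        out = variance_explained(activity, {"ramp": w}, baseline=np.zeros(8))
        assert out["ramp"] == pytest.approx(1.0)

    def test_orthonormal_modes_bessel(self, rng):
        A = rng.normal(size=(10, 30))
        Q, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        modes = {f"m{k}": Q[:, k] for k in range(3)}
        out = variance_explained(A, modes, baseline=np.zeros(10))
        assert sum(out.values()) <= 1.0 + 1e-12

    def test_planted_power_shares_recovered(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(20, 3)))
        shares = np.array([0.5, 0.3, 0.2])
        coefs = np.sqrt(shares)[:, None] * rng.normal(size=(3, 200))
        A = Q @ coefs
        out = variance_explained(A, {f"m{k}": Q[:, k] for k in range(3)},
                                 baseline=np.zeros(20))
        got = np.array([out[f"m{k}"] for k in range(3)])
        assert np.allclose(got / got.sum(), shares, atol=0.05)


class TestModeAngle:
    def test_identical_vectors(self, rng):
        v = rng.normal(size=20)
        out = mode_angle(v, v.copy(), n_shuffles=100, seed=0)
        assert out["cosine"] == pytest.approx(1.0)
        assert out["significant"]

    def test_orthogonal_vectors(self):
        a = np.zeros(10); a[0] = 1.0
        b = np.zeros(10); b[1] = 1.0
        out = mode_angle(a, b, n_shuffles=100, seed=0)
        assert out["cosine"] == pytest.approx(0.0)

    def test_random_high_dim_vectors_rarely_significant(self, rng):
        hits = 0
        for _ in range(40):
            a, b = rng.normal(size=(2, 100))
            out = mode_angle(a, b, n_shuffles=200, seed=1)
            assert abs(out["cosine"]) < 0.4
            hits += out["significant"]
        assert hits <= 8  # ~5% nominal, allow slack


class TestPopulationCorrelation:
    def test_self_comparison_peaks_on_diagonal(self, rng):
        act = rng.normal(5, 1, size=(12, 10)) + np.linspace(0, 5, 10)
        out = population_correlation_analysis(act, act, threshold=0.8)
        assert np.allclose(out["peak_index"], np.arange(10))

    def test_time_scaled_comparison_slope(self, rng):
        # comparison unfolds 1.25x slower: peak trace slope ~ 0.8
        t_ref = np.linspace(0, 1, 20)
        pattern = rng.normal(size=(30, 1)) * np.sin(np.pi * t_ref)[None, :] + \
            rng.normal(size=30)[:, None] * t_ref[None, :]
        t_comp = np.linspace(0, 1, 25)  # same pattern over 1.25x the bins
        comp = np.stack([np.interp(t_comp / t_comp[-1], t_ref, row) for row in pattern])
        out = population_correlation_analysis(pattern, comp, threshold=0.8)
        ok = np.isfinite(out["peak_index"])
        slope = np.polyfit(np.arange(20)[ok], out["peak_index"][ok], 1)[0]
        assert slope == pytest.approx(1.25, abs=0.15)

    def test_low_correlation_columns_missing(self, rng):
        ref = rng.normal(size=(10, 5))
        comp = rng.normal(size=(10, 5))
        out = population_correlation_analysis(ref, comp, threshold=0.99)
        assert np.isnan(out["peak_index"]).all()

    def test_needs_two_units(self, rng):
        with pytest.raises(ValueError):
            population_correlation_analysis(rng.normal(size=(1, 5)), rng.normal(size=(1, 5)))


class TestVectorField:
    @staticmethod
    def _drift_data(reverse_stim):
        # control flow: straight +Y drift at X ~ 1.6 (away from the origin line)
        n_trials, n_bins = 60, 40
        X = np.full((n_trials, n_bins), 1.6)
        Y = np.tile(np.linspace(0.1, 3.9, n_bins), (n_trials, 1))
        stim = np.zeros(n_trials, bool)
        stim[40:] = True
        if reverse_stim:
            Y[40:] = Y[40:, ::-1]
        lick_bin = np.full(n_trials, n_bins - 1)
        return X, Y, lick_bin, stim

    def test_reversed_flow_gives_pi_angle(self):
        X, Y, lick_bin, stim = self._drift_data(reverse_stim=True)
        out = vector_field_2d(X, Y, lick_bin, stim, (0, 39), min_points=10)
        diffs = np.abs(list(out["angle_diff"].values()))
        assert len(diffs) > 0
        assert np.allclose(diffs, np.pi, atol=1e-6)

    def test_identical_flow_zero_angle(self):
        X, Y, lick_bin, stim = self._drift_data(reverse_stim=False)
        out = vector_field_2d(X, Y, lick_bin, stim, (0, 39), min_points=10)
        diffs = np.abs(list(out["angle_diff"].values()))
        assert np.allclose(diffs, 0.0, atol=1e-6)

    def test_sparse_bins_omitted(self):
        X, Y, lick_bin, stim = self._drift_data(reverse_stim=False)
        out = vector_field_2d(X, Y, lick_bin, stim, (0, 39), min_points=10**6)
        assert len(out["control_field"]) == 0

    def test_radial_flow_excluded(self):
        # flow along the through-origin direction must be excluded
        n_trials, n_bins = 40, 30
        r = np.tile(np.linspace(0.2, 4.0, n_bins), (n_trials, 1))
        X = r * np.cos(0.5)
        Y = r * np.sin(0.5)
        stim = np.zeros(n_trials, bool)
        stim[20:] = True
        lick_bin = np.full(n_trials, n_bins - 1)
        out = vector_field_2d(X, Y, lick_bin, stim, (0, 29), min_points=5)
        assert len(out["angle_diff"]) == 0
        assert len(out["excluded_bins"]) > 0


class TestPseudoSession:
    def test_inclusion_and_disjointness(self):
        sessions = []
        for k in range(2):
            s, _ = make_session(
                behavior=BehaviorGenConfig(n_trials=400),
                neural=NeuralGenConfig(n_units=6),
                seed=20 + k, session_id=f"s{k}",
            )
            sessions.append(s)
        out = assemble_pseudo_session(sessions, seed=0)
        # excluded units carry a reason; included units have group activity
        assert out["group_activity"].shape[1] == 6
        for uid, reason in out["excluded"].items():
            assert isinstance(reason, str) and reason
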