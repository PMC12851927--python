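import numpy as np
import pytest

from cbgtimer.core import PerturbationSpec, Session, Trial, Unit


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_trials(lick_times, delays=None, cue=None, perturbed=None):
    """Build a trial list from a lick-time vector (NaN = no lick)."""
    n = len(lick_times)
    delays = delays if delays is not None else [1.0] * n
    cue = cue if cue is not None else [True] * n
    perturbed = perturbed if perturbed is not None else [False] * n
    trials = []
    for i, lt in enumerate(lick_times):
        licked = lt is not None and np.isfinite(lt)
        trials.append(
            Trial(
                index=i,
                delay_duration=delays[i],
                first_lick_time=float(lt) if licked else None,
                rewarded=bool(licked and lt >= delays[i] and cue[i]),
                cue_present=bool(cue[i]),
                perturbation=PerturbationSpec(target="ALM") if perturbed[i] else None,
            )
        )
    return trials


@pytest.fixture
def tiny_session():
    """3 trials, 2 units with hand-placed spikes."""
    trials = make_trials([1.0, np.nan, 1.5])
    onsets = np.array([0.0, 10.0, 20.0])
    units = [
        Unit("u0", "ALM", np.array([0.5, 10.2, 20.7]), mean_rate=1.0,
             spike_width=0.6),
        Unit("u1", "VLS", np.array([0.25, 0.75, 21.0]), mean_rate=2.0,
             spike_width=0.45, post_spike_suppression=30.0, long_isi_fraction=0.02),
    ]
    return Session(animal_id="m1", session_id="s1", trials=trials,
                   cue_onsets=onsets, units=units)


@pytest.fixture(scope="session")
def synth_session():
    """A moderate synthetic session shared by read-only tests."""
    from cbgtimer.synth import BehaviorGenConfig, NeuralGenConfig, make_session

    session, truth = make_session(
        behavior=BehaviorGenConfig(n_trials=300),
        neural=NeuralGenConfig(n_units=15),
        seed=42,
    )
    return session, truth
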