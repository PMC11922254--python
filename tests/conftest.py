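import numpy as np
import pytest

from ephys_context import synth
from ephys_context.session_model import StimulusEpoch
from ephys_context.spike_metrics import TrialResponseSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_series(fr, blfr, stimulus="BOS", context="solitary",
                presentation_index=None) -> TrialResponseSeries:
    fr = np.asarray(fr, float)
    if presentation_index is None:
        presentation_index = np.arange(len(fr))
    return TrialResponseSeries("u0", stimulus, context, fr,
                               np.asarray(blfr, float),
                               np.asarray(presentation_index))


@pytest.fixture
def series_factory():
    return make_series


def make_epoch(onset, offset, stimulus="BOS", context="solitary",
               trial_id=0, motifs=None, source="playback") -> StimulusEpoch:
    if motifs is None:
        motifs = ([(onset, offset)] if stimulus == "WN"
                  else [(onset, (onset + offset) / 2),
                        ((onset + offset) / 2, offset)])
    return StimulusEpoch(trial_id, stimulus, context, onset, offset,
                         motifs, source)


@pytest.fixture
def epoch_factory():
    return make_epoch


@pytest.fixture
def small_session_config():
    """Four units (two BS, two NS) over a short two-context schedule."""
    units = synth.make_population(4, seed=7)
    return synth.SessionSimConfig(
        n_trials_per_stimulus=12, units=units, seed=11,
        lfp=synth.LfpSimParams(
            band_effects=[("CON", "solitary", 10.0, 4.0, 4.0)]))


@pytest.fixture
def small_session(small_session_config):
    return synth.generate_session(small_session_config)
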