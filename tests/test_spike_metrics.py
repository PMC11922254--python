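import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ephys_context import spike_metrics as spm
from ephys_context import synth
from ephys_context.session_model import SpikeTrain, Waveform

from .oracles import dprime_oracle, rs_oracle, ssa_oracle, z_oracle


def train(times, duration=100.0, unit_id="u0"):
    return SpikeTrain(unit_id, np.asarray(times, float), duration)


# ---------------------------------------------------------------------------
# waveform width and classification
# ---------------------------------------------------------------------------

def test_width_index_arithmetic():
    samples = np.zeros(64)
    samples[30] = -1.0
    samples[45] = 0.8
    w = Waveform("u0", samples + 0.0, 30000.0)
    assert spm.peak_to_peak_width(w) == pytest.approx(15 / 30000 * 1e3)
    assert spm.peak_to_peak_width(w) == pytest.approx(0.5)


def test_single_negative_lobe_is_shape_error():
    t = np.arange(64)
    samples = -np.exp(-0.5 * ((t - 32) / 4.0) ** 2)
    with pytest.raises(spm.WaveformShapeError):
        spm.peak_to_peak_width(Waveform("u0", samples, 30000.0))


def test_single_positive_lobe_is_shape_error():
    t = np.arange(64)
    samples = np.exp(-0.5 * ((t - 32) / 4.0) ** 2)
    with pytest.raises(spm.WaveformShapeError):
        spm.peak_to_peak_width(Waveform("u0", samples, 30000.0))


def test_trough_at_end_is_shape_error():
    samples = -np.linspace(0.1, 1.0, 16)
    with pytest.raises(spm.WaveformShapeError):
        spm.peak_to_peak_width(Waveform("u0", samples, 30000.0))


def test_synth_waveform_width_roundtrip():
    unit = synth.UnitSimParams("u0", {"solitary": 5.0},
                               waveform_width_ms=0.43)
    w = synth.generate_waveform(unit, seed=0)
    assert spm.peak_to_peak_width(w) == pytest.approx(0.43, abs=1 / 30.0)


@pytest.mark.parametrize("width,expected", [
    (0.50, "BS"),
    (0.30, "NS"),
    (0.43, "NS"),          # boundary goes to NS (strict > for BS)
])
def test_classify_unit(width, expected):
    assert spm.classify_unit(width) == expected


def test_classify_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        spm.classify_unit(0.0)


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def test_motif_rate_basic():
    t = train([1.0, 1.1, 1.2, 1.3, 1.4])
    assert spm.motif_rate(t, (1.0, 1.5)) == pytest.approx(10.0)


def test_motif_rate_empty_window():
    assert spm.motif_rate(train([5.0]), (1.0, 1.5)) == 0.0


def test_motif_rate_half_open_boundary():
    t = train([1.0, 1.5])                  # spike exactly at end excluded
    assert spm.motif_rate(t, (1.0, 1.5)) == pytest.approx(2.0)


def test_motif_rate_rejects_degenerate_window():
    with pytest.raises(ValueError):
        spm.motif_rate(train([1.0]), (1.0, 1.0))


def test_baseline_rate_playback(epoch_factory):
    epoch = epoch_factory(10.0, 12.0)
    t = train([8.1, 8.5, 8.9])             # inside [8, 9)
    assert spm.baseline_rate_playback(t, epoch) == pytest.approx(3.0)


def test_baseline_buffer_excluded(epoch_factory):
    epoch = epoch_factory(10.0, 12.0)
    t = train([9.1, 9.5, 9.9])             # buffer second, not baseline
    assert spm.baseline_rate_playback(t, epoch) == 0.0


def test_baseline_too_early_errors(epoch_factory):
    epoch = epoch_factory(1.5, 3.0)
    with pytest.raises(ValueError):
        spm.baseline_rate_playback(train([0.5]), epoch)


def test_vocal_baseline_uniform_train(epoch_factory, rng):
    times = np.sort(rng.uniform(0, 200, 2000))      # ~10 Hz homogeneous
    bout = [epoch_factory(50.0, 54.0, source="vocalization")]
    rate = spm.baseline_rate_vocal(train(times, 200.0), bout, window_s=5.0)
    assert rate == pytest.approx(10.0, rel=0.25)


def test_vocal_baseline_buffer_excluded(epoch_factory):
    bout = [epoch_factory(50.0, 54.0, source="vocalization")]
    # spikes only within 1.5 s of the bout edges
    t = train([48.6, 49.0, 54.5, 55.0], 100.0)
    assert spm.baseline_rate_vocal(t, bout) == 0.0


def test_vocal_baseline_single_motif_bout(epoch_factory):
    bout = [epoch_factory(50.0, 51.0, motifs=[(50.0, 51.0)],
                          source="vocalization")]
    t = train([48.2, 52.8], 100.0)
    assert spm.baseline_rate_vocal(t, bout) == pytest.approx(1.0)


def test_vocal_baseline_outside_session_errors(epoch_factory):
    bout = [epoch_factory(1.0, 2.0)]
    with pytest.raises(ValueError):
        spm.baseline_rate_vocal(train([0.5], 100.0), bout)


# ---------------------------------------------------------------------------
# z score
# ---------------------------------------------------------------------------

def test_z_score_worked_example(series_factory):
    s = series_factory([10.0, 12.0], [7.0, 5.0])
    assert spm.z_score(s) == pytest.approx(5.0 / math.sqrt(8.0), abs=1e-12)
    assert spm.z_score(s) == pytest.approx(1.7677669529, abs=1e-9)


def test_z_score_identical_series_zero(series_factory):
    s = series_factory([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
    assert spm.z_score(s) == 0.0


def test_z_score_translation_invariance(series_factory, rng):
    fr = rng.normal(10, 2, 20)
    blfr = rng.normal(5, 1, 20)
    base = spm.z_score(series_factory(fr, blfr))
    shifted = spm.z_score(series_factory(fr + 7.5, blfr + 7.5))
    assert shifted == pytest.approx(base, abs=1e-12)


def test_z_score_needs_two_pairs(series_factory):
    with pytest.raises(ValueError):
        spm.z_score(series_factory([4.0], [1.0]))


def test_z_score_undefined_flag(series_factory):
    # constant nonzero difference: denominator 0, numerator != 0
    s = series_factory([6.0, 8.0], [3.0, 5.0])
    assert spm.z_score(s) is None


def test_z_score_no_sqrt_variant(series_factory):
    s = series_factory([10.0, 12.0], [7.0, 5.0])
    assert spm.z_score(s, sqrt_denominator=False) == \
        pytest.approx(5.0 / 8.0, abs=1e-12)


def test_z_score_matches_oracle(series_factory, rng):
    for _ in range(200):
        n = int(rng.integers(2, 30))
        fr = rng.normal(10, 3, n)
        blfr = rng.normal(5, 2, n)
        got = spm.z_score(series_factory(fr, blfr))
        want = z_oracle(list(fr), list(blfr))
        assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# response strength and d'
# ---------------------------------------------------------------------------

def test_rs_worked_example(series_factory):
    assert spm.response_strength(
        series_factory([10.0, 12.0], [7.0, 5.0])) == pytest.approx(5.0)


def test_rs_zero_and_single(series_factory):
    assert spm.response_strength(series_factory([4.0], [4.0])) == 0.0
    assert spm.response_strength(series_factory([4.0], [1.0])) == 3.0


def test_dprime_worked_example(series_factory):
    a = series_factory([5.0, 5.0, 7.0, 7.0], [0.0] * 4)
    b = series_factory([1.0, 1.0, 3.0, 3.0], [0.0] * 4, stimulus="CON")
    got = spm.d_prime(a, b)
    assert got == pytest.approx(2 * 4 / math.sqrt(8 / 3), abs=1e-12)
    assert got == pytest.approx(4.8989794855, abs=1e-9)


def test_dprime_diagonal_zero(series_factory):
    a = series_factory([5.0, 6.0, 7.0], [1.0, 2.0, 1.0])
    assert spm.d_prime(a, a) == 0.0


def test_dprime_antisymmetry(series_factory, rng):
    a = series_factory(rng.normal(10, 2, 12), rng.normal(4, 1, 12))
    b = series_factory(rng.normal(6, 2, 12), rng.normal(4, 1, 12),
                       stimulus="WN")
    assert spm.d_prime(a, b) == pytest.approx(-spm.d_prime(b, a), abs=1e-12)


def test_dprime_undefined_flag(series_factory):
    a = series_factory([5.0, 5.0], [1.0, 1.0])
    b = series_factory([2.0, 2.0], [1.0, 1.0], stimulus="WN")
    assert spm.d_prime(a, b) is None


@settings(max_examples=50, deadline=None)
@given(arrays(float, 6, elements=st.floats(-50, 50)),
       arrays(float, 6, elements=st.floats(-50, 50)))
def test_dprime_antisymmetry_property(fr_a, fr_b):
    from .conftest import make_series
    a = make_series(fr_a, np.zeros(6))
    b = make_series(fr_b, np.zeros(6), stimulus="CON")
    ab = spm.d_prime(a, b)
    ba = spm.d_prime(b, a)
    if ab is None:
        assert ba is None
    else:
        assert ab == pytest.approx(-ba, abs=1e-9)
    assert spm.d_prime(a, a) == 0.0


# ---------------------------------------------------------------------------
# SSA
# ---------------------------------------------------------------------------

def test_ssa_adapting_at_half(series_factory):
    fr = [10.0] * 5 + [5.0] * 5
    s = series_factory(fr, [0.0] * 10)
    assert spm.ssa_ratio(s) == pytest.approx(0.5)


def test_ssa_constant_is_one(series_factory):
    s = series_factory([7.0] * 12, [0.0] * 12)
    assert spm.ssa_ratio(s) == pytest.approx(1.0)


def test_ssa_threshold_rule(series_factory):
    adapting = series_factory([10.0] * 5 + [5.0] * 5, [0.0] * 10)
    retained = series_factory([10.0] * 5 + [7.0] * 5, [0.0] * 10)
    assert spm.ssa_ratio(adapting) < spm.SSA_THRESHOLD
    assert spm.ssa_ratio(retained) > spm.SSA_THRESHOLD


def test_ssa_needs_ten_presentations(series_factory):
    with pytest.raises(ValueError):
        spm.ssa_ratio(series_factory([1.0] * 9, [0.0] * 9))


def test_ssa_undefined_when_first_five_silent(series_factory):
    s = series_factory([0.0] * 5 + [5.0] * 5, [0.0] * 10)
    assert spm.ssa_ratio(s) is None


def test_ssa_collapses_motifs_per_presentation(series_factory):
    # two motifs per presentation; per-presentation means drive the ratio
    fr, idx = [], []
    for k in range(10):
        rate = 10.0 if k < 5 else 5.0
        fr += [rate - 1.0, rate + 1.0]
        idx += [k, k]
    s = series_factory(fr, [0.0] * 20, presentation_index=idx)
    assert spm.ssa_ratio(s) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# offset responses
# ---------------------------------------------------------------------------

def test_offset_ratio_examples():
    t = train([12.1, 12.3, 12.5])
    assert spm.offset_ratio(t, 12.0, 3.0) == pytest.approx(1.0)
    t6 = train(np.linspace(12.0, 12.9, 6))
    assert spm.offset_ratio(t6, 12.0, 3.0) == pytest.approx(2.0)


def test_offset_ratio_zero_baseline_undefined():
    assert spm.offset_ratio(train([12.5]), 12.0, 0.0) is None


def test_offset_z_matches_z_on_offset_series(series_factory):
    s = series_factory([6.0, 8.0], [3.0, 5.0])
    assert spm.offset_z(s) is None          # degenerate denominator
    s2 = series_factory([6.0, 9.0], [3.0, 5.0])
    assert spm.offset_z(s2) == spm.z_score(s2)


def test_offset_z_sign_flips_with_roles(series_factory, rng):
    fr = rng.normal(8, 2, 15)
    blfr = rng.normal(4, 1, 15)
    fwd = spm.offset_z(series_factory(fr, blfr))
    rev = spm.offset_z(series_factory(blfr, fr))
    assert fwd == pytest.approx(-rev, abs=1e-12)


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------

def test_responsive_forced_separation(series_factory, rng):
    blfr = rng.normal(5, 0.5, 20)
    s = series_factory(blfr + 10.0 + rng.normal(0, 0.1, 20), blfr)
    assert spm.is_responsive(s)


def test_responsive_single_pair_errors(series_factory):
    with pytest.raises(ValueError):
        spm.is_responsive(series_factory([4.0], [1.0]))


def test_all_zero_differences_non_responsive(series_factory):
    s = series_factory([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
    assert not spm.is_responsive(s)


def test_responsive_type_one_error_rate(series_factory, rng):
    flagged = 0
    n_units = 400
    for _ in range(n_units):
        fr = rng.normal(5, 1, 20)
        blfr = rng.normal(5, 1, 20)
        flagged += spm.is_responsive(series_factory(fr, blfr))
    assert 0.02 <= flagged / n_units <= 0.09


# ---------------------------------------------------------------------------
# selection filter
# ---------------------------------------------------------------------------

def _metrics(responsive, ssa_values):
    per = {}
    for i, ssa in enumerate(ssa_values):
        per[(["BOS", "BOS_REV", "CON", "WN"][i], "solitary")] = \
            spm.StimulusContextMetrics(12, 10.0, 5.0, 1.0, 5.0, ssa, 1.0, 0.1)
    return spm.UnitMetrics("u0", "BS", responsive, per, {})


def test_select_retains_any_stimulus_above_threshold():
    m = _metrics(True, [0.9, 0.2, 0.1, 0.1])
    assert spm.select_analysis_units([m]) == [m]


def test_select_excludes_all_low_ssa():
    m = _metrics(True, [0.6, 0.5, 0.2, 0.1])     # 0.6 is not > 0.6
    assert spm.select_analysis_units([m]) == []


def test_select_requires_responsiveness():
    m = _metrics(False, [0.95, 0.9, 0.9, 0.9])
    assert spm.select_analysis_units([m]) == []


# ---------------------------------------------------------------------------
# series construction and orchestration
# ---------------------------------------------------------------------------

def test_build_series_pairs_motifs_with_trial_baseline(epoch_factory):
    epochs = [epoch_factory(10.0, 12.0, trial_id=0),
              epoch_factory(20.0, 22.0, trial_id=1)]
    t = train([8.5, 10.2, 10.4, 11.5, 21.2], 30.0)
    s = spm.build_response_series(t, epochs, "BOS", "solitary")
    assert len(s) == 4                          # 2 trials x 2 motifs
    np.testing.assert_allclose(s.blfr_hz, [1.0, 1.0, 0.0, 0.0])
    np.testing.assert_allclose(s.fr_hz, [2.0, 1.0, 0.0, 1.0])
    assert list(s.presentation_index) == [0, 0, 1, 1]


def test_build_series_missing_combo_is_none(epoch_factory):
    epochs = [epoch_factory(10.0, 12.0)]
    t = train([1.0], 30.0)
    assert spm.build_response_series(t, epochs, "WN", "social") is None


def test_match_playback_trials_subsamples(epoch_factory):
    epochs = [epoch_factory(10.0 + 5 * k, 12.0 + 5 * k, trial_id=k)
              for k in range(10)]
    subset = spm.match_playback_trials(epochs, 4, seed=3)
    assert len(subset) == 4
    assert [e.trial_id for e in subset] == sorted(e.trial_id for e in subset)
    again = spm.match_playback_trials(epochs, 4, seed=3)
    assert [e.trial_id for e in subset] == [e.trial_id for e in again]
    assert spm.match_playback_trials(epochs, 20, seed=0) == epochs


def test_compute_unit_metrics_structure(small_session):
    log = {}
    metrics = spm.compute_unit_metrics(small_session, exclusion_log=log)
    assert len(metrics) == len(small_session.spike_trains)
    m = metrics[0]
    assert set(m.per_stimulus) == {(s, c) for s in
                                   ("BOS", "BOS_REV", "CON", "WN")
                                   for c in ("solitary", "social")}
    for (a, b, ctx), val in m.d_prime.items():
        if a == b:
            assert val == 0.0
        else:
            rev = m.d_prime[(b, a, ctx)]
            if val is not None and rev is not None:
                assert val == pytest.approx(-rev, abs=1e-9)


def test_gain_monotonicity_in_z_and_rs(epoch_factory):
    """Raising evoked gain raises the median estimated Z and RS."""
    gains = [1.3, 2.0, 3.5]
    medians_z, medians_rs = [], []
    for gain in gains:
        zs, rss = [], []
        for rep in range(8):
            epochs = [epoch_factory(10.0 + 7.0 * k, 12.0 + 7.0 * k,
                                    trial_id=k) for k in range(50)]
            unit = synth.UnitSimParams(
                f"u{rep}", {"solitary": 8.0},
                evoked_gain={("BOS", "solitary"): gain})
            t = synth.generate_spike_train(unit, epochs,
                                           epochs[-1].offset_s + 5.0,
                                           seed=rep)
            s = spm.build_response_series(t, epochs, "BOS", "solitary")
            zs.append(spm.z_score(s))
            rss.append(spm.response_strength(s))
        medians_z.append(np.median(zs))
        medians_rs.append(np.median(rss))
    assert medians_z[0] < medians_z[1] < medians_z[2]
    assert medians_rs[0] < medians_rs[1] < medians_rs[2]


def test_formula_oracles_random_sample(series_factory, rng):
    for _ in range(200):
        n = int(rng.integers(2, 25))
        fr_a = rng.gamma(4, 2, n)
        bl_a = rng.gamma(2, 2, n)
        fr_b = rng.gamma(3, 2, n)
        bl_b = rng.gamma(2, 2, n)
        a = series_factory(fr_a, bl_a)
        b = series_factory(fr_b, bl_b, stimulus="CON")
        assert spm.response_strength(a) == \
            pytest.approx(rs_oracle(fr_a, bl_a), abs=1e-12)
        assert spm.d_prime(a, b) == pytest.approx(
            dprime_oracle(fr_a, bl_a, fr_b, bl_b), abs=1e-12)
        if n >= 10:
            assert spm.ssa_ratio(a) == \
                pytest.approx(ssa_oracle(list(fr_a)), abs=1e-12)
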