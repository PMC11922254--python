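"""Synthetic session generator.

Builds complete :class:`~ephys_context.session_model.Session` objects with the
statistical structure the analysis stages assume: block-randomized playback of
the four stimulus classes in two contexts, inhomogeneous-Poisson units with
baseline / evoked / trialwise-adapting / offset firing, biphasic mean
waveforms of controlled trough-to-peak width, and multichannel 1/f LFP with
line noise and stimulus-locked band power.

Everything is deterministic under the configured seed; each unit and each LFP
channel draws from its own stream derived from ``(seed, name)`` so adding a
unit never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session_model import (LFPRecording, Session, SpikeTrain, StimulusEpoch,
                            Waveform)

STIMULI = ("BOS", "BOS_REV", "CON", "WN")

#: post-offset window (s) during which offset_gain applies
OFFSET_WINDOW_S = 1.0


class ConfigError(ValueError):
    """A simulation config violates one of its invariants."""


def _rng_for(seed: int, name: str) -> np.random.Generator:
    # crc32 gives a stable 32-bit key per name, independent of hash seeding
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class UnitSimParams:
    """Ground-truth firing structure for one simulated unit.

    ``evoked_gain[(stimulus, context)]`` multiplies the context baseline
    during motif windows; the k-th presentation (k = 0, 1, ...) of a stimulus
    is additionally scaled by
    ``adaptation_floor + (1 - adaptation_floor) * exp(-k / adaptation_tau_trials)``.
    ``offset_gain[context]`` multiplies baseline for 1 s after each offset.
    """

    unit_id: str
    baseline_rate_hz: dict[str, float]
    evoked_gain: dict[tuple[str, str], float] = field(default_factory=dict)
    adaptation_floor: float = 1.0
    adaptation_tau_trials: float = 10.0
    offset_gain: dict[str, float] = field(default_factory=dict)
    waveform_width_ms: float = 0.6
    waveform_sampling_hz: float = 30000.0
    unit_class: Optional[str] = None
    refractory_s: float = 0.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.baseline_rate_hz.values()):
            raise ConfigError("baseline rates must be >= 0")
        if any(g < 0 for g in self.evoked_gain.values()):
            raise ConfigError("evoked gains must be >= 0")
        if not (0.0 < self.adaptation_floor <= 1.0):
            raise ConfigError("adaptation_floor must lie in (0, 1]")
        if self.adaptation_tau_trials <= 0:
            raise ConfigError("adaptation_tau_trials must be positive")
        if self.waveform_width_ms <= 0:
            raise ConfigError("waveform_width_ms must be positive")


@dataclass
class LfpSimParams:
    """Ground truth for the simulated field potential."""

    n_channels: int = 4
    sampling_rate_hz: float = 500.0
    noise_spectrum_exponent: float = 1.0
    line_hz: float = 60.0
    line_amplitude: float = 0.5
    #: (stimulus, context, center_hz, bandwidth_hz, power_gain)
    band_effects: list[tuple[str, str, float, float, float]] = \
        field(default_factory=list)
    band_base_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("need at least one LFP channel")
        for stim, ctx, center, bw, gain in self.band_effects:
            if center + bw / 2 > 50.0:
                raise ConfigError(
                    f"band effect ({stim},{ctx}) exceeds the 0-50 Hz "
                    "analysis range")
            if gain < 0:
                raise ConfigError("power_gain must be >= 0")


@dataclass
class SessionSimConfig:
    """Full recipe for one synthetic session."""

    n_trials_per_stimulus: int = 25
    stimulus_duration_s: float = 2.0
    motifs_per_song: int = 2
    inter_trial_interval_s: float = 5.0
    contexts: tuple[str, ...] = ("solitary", "social")
    stimuli: tuple[str, ...] = STIMULI
    units: list[UnitSimParams] = field(default_factory=list)
    lfp: Optional[LfpSimParams] = None
    seed: int = 0
    lead_in_s: float = 5.0

    def __post_init__(self) -> None:
        # 4.5 s keeps the 2 s-before baseline and 1 s offset windows clear of
        # neighbouring stimuli
        if self.inter_trial_interval_s < 4.5:
            raise ConfigError("inter_trial_interval_s must be >= 4.5 s")
        if self.n_trials_per_stimulus < 5:
            raise ConfigError(
                "n_trials_per_stimulus must be >= 5 (SSA uses the first and "
                "last five presentations)")
        if self.lead_in_s < 3.0:
            raise ConfigError("lead_in_s must leave room for baseline windows")


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def generate_epochs(config: SessionSimConfig) -> list[StimulusEpoch]:
    """Block-randomized playback schedule, first context block first.

    Within every block the stimulus order is shuffled; blocks of one context
    are exhausted before the next context starts (the study's fixed
    solitary-then-social order).
    """
    rng = _rng_for(config.seed, "epochs")
    epochs = []
    t = config.lead_in_s
    trial_id = 0
    for context in config.contexts:
        for _ in range(config.n_trials_per_stimulus):
            order = list(config.stimuli)
            rng.shuffle(order)
            for stimulus in order:
                onset = t
                offset = onset + config.stimulus_duration_s
                if stimulus == "WN":
                    motifs = [(onset, offset)]
                else:
                    edges = np.linspace(onset, offset,
                                        config.motifs_per_song + 1)
                    motifs = list(zip(edges[:-1], edges[1:]))
                epochs.append(StimulusEpoch(
                    trial_id=trial_id, stimulus=stimulus, context=context,
                    onset_s=onset, offset_s=offset,
                    motif_bounds=[(float(a), float(b)) for a, b in motifs],
                    source="playback"))
                trial_id += 1
                t = offset + config.inter_trial_interval_s
    return epochs


def session_duration(config: SessionSimConfig,
                     epochs: Sequence[StimulusEpoch]) -> float:
    return epochs[-1].offset_s + config.inter_trial_interval_s


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _rate_profile(unit: UnitSimParams, epochs: Sequence[StimulusEpoch],
                  duration_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate function as (edges, rates).

    ``edges`` has length ``len(rates) + 1``; rate ``rates[i]`` applies on
    ``[edges[i], edges[i+1])``.  Inter-trial time takes the baseline of the
    upcoming epoch's context (trailing time: the last epoch's context).
    """
    edges = [0.0]
    rates = []
    presentation_count: dict[tuple[str, str], int] = {}
    ordered = sorted(epochs, key=lambda e: e.onset_s)

    def push(end: float, rate: float) -> None:
        if end > edges[-1]:
            edges.append(end)
            rates.append(rate)

    for epoch in ordered:
        base = unit.baseline_rate_hz.get(epoch.context, 0.0)
        push(epoch.onset_s, base)
        key = (epoch.stimulus, epoch.context)
        k = presentation_count.get(key, 0)
        presentation_count[key] = k + 1
        gain = unit.evoked_gain.get(key, 1.0)
        adapt = (unit.adaptation_floor
                 + (1.0 - unit.adaptation_floor)
                 * np.exp(-k / unit.adaptation_tau_trials))
        for start, end in epoch.motif_bounds:
            push(start, base)                      # pre/inter-motif gap
            push(end, base * gain * adapt)
        push(epoch.offset_s, base)
        push(min(epoch.offset_s + OFFSET_WINDOW_S, duration_s),
             base * unit.offset_gain.get(epoch.context, 1.0))
    if ordered:
        last_base = unit.baseline_rate_hz.get(ordered[-1].context, 0.0)
    else:
        # epoch-free stretch has no context; average the baseline map
        values = list(unit.baseline_rate_hz.values())
        last_base = float(np.mean(values)) if values else 0.0
    push(duration_s, last_base)
    return np.asarray(edges), np.asarray(rates)


def generate_spike_train(unit: UnitSimParams,
                         epochs: Sequence[StimulusEpoch],
                         duration_s: float, seed: int) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning a piecewise-constant rate."""
    rng = _rng_for(seed, f"spikes/{unit.unit_id}")
    edges, rates = _rate_profile(unit, epochs, duration_s)
    rate_max = float(rates.max(initial=0.0))
    if rate_max == 0.0:
        return SpikeTrain(unit.unit_id, np.empty(0), duration_s)
    n_cand = rng.poisson(rate_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    idx = np.clip(np.searchsorted(edges, cand, "right") - 1, 0,
                  len(rates) - 1)
    keep = rng.uniform(0.0, 1.0, n_cand) < rates[idx] / rate_max
    times = cand[keep]
    if unit.refractory_s > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= unit.refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(unit.unit_id, times, duration_s)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def generate_waveform(unit: UnitSimParams, seed: int) -> Waveform:
    """Biphasic template: negative trough, then a positive peak exactly
    ``waveform_width_ms`` later (to the nearest sample)."""
    fs = unit.waveform_sampling_hz
    width_samples = round(unit.waveform_width_ms * 1e-3 * fs)
    if width_samples < 1:
        raise ConfigError(
            f"width {unit.waveform_width_ms} ms is below one sample at "
            f"{fs} Hz")
    rng = _rng_for(seed, f"waveform/{unit.unit_id}")
    window_s = max(4e-3, 2.5 * unit.waveform_width_ms * 1e-3)
    n = int(round(window_s * fs))
    t = np.arange(n)
    trough_idx = n // 3
    peak_idx = trough_idx + width_samples
    if peak_idx >= n:
        n = peak_idx + trough_idx
        t = np.arange(n)
    sigma = max(width_samples / 4.0, 1.0)
    wave = (-1.0 * np.exp(-0.5 * ((t - trough_idx) / sigma) ** 2)
            + 0.55 * np.exp(-0.5 * ((t - peak_idx) / (1.3 * sigma)) ** 2))
    wave += 0.005 * rng.standard_normal(n)
    # pin the extrema so noise can never move the measured trough/peak
    wave[trough_idx] = wave.min() - 0.03
    wave[peak_idx] = wave.max() + 0.03
    return Waveform(unit.unit_id, wave, fs)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                center: float, bandwidth: float) -> np.ndarray:
    """Unit-variance noise restricted to [center-bw/2, center+bw/2]."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = ((freqs >= center - bandwidth / 2)
            & (freqs <= center + bandwidth / 2))
    out = np.fft.irfft(spec * mask, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_lfp(params: LfpSimParams, epochs: Sequence[StimulusEpoch],
                 duration_s: float, seed: int) -> LFPRecording:
    """1/f^alpha background + line sinusoid + stimulus-locked band power.

    Each band effect contributes band-limited noise whose amplitude is
    ``band_base_amplitude`` outside and
    ``band_base_amplitude * sqrt(power_gain)`` inside matching stimulus
    envelopes, so spectral *power* in the band scales by ``power_gain``
    during those stimuli.
    """
    fs = params.sampling_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    channels = [f"ch{i:02d}" for i in range(params.n_channels)]
    signal = np.empty((params.n_channels, n))
    for ci, name in enumerate(channels):
        rng = _rng_for(seed, f"lfp/{name}")
        x = _colored_noise(rng, n, fs, params.noise_spectrum_exponent)
        # per-channel phase so the line survives common-average referencing
        x = x + params.line_amplitude * np.sin(
            2 * np.pi * params.line_hz * t + rng.uniform(0, 2 * np.pi))
        for stim, ctx, center, bw, gain in params.band_effects:
            env = np.full(n, params.band_base_amplitude)
            for epoch in epochs:
                if epoch.stimulus == stim and epoch.context == ctx:
                    i0 = int(round(epoch.onset_s * fs))
                    i1 = int(round(epoch.offset_s * fs))
                    env[i0:i1] = params.band_base_amplitude * np.sqrt(gain)
            x = x + env * _band_noise(rng, n, fs, center, bw)
        signal[ci] = x
    return LFPRecording(channels, signal, fs)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def generate_session(config: SessionSimConfig,
                     session_id: str = "synthetic") -> Session:
    epochs = generate_epochs(config)
    duration = session_duration(config, epochs)
    trains = [generate_spike_train(u, epochs, duration, config.seed)
              for u in config.units]
    waveforms = [generate_waveform(u, config.seed) for u in config.units]
    lfp = None
    if config.lfp is not None:
        lfp = generate_lfp(config.lfp, epochs, duration, config.seed)
    return Session(session_id=session_id, epochs=epochs, spike_trains=trains,
                   waveforms=waveforms, lfp=lfp,
                   metadata={"seed": config.seed})


# ---------------------------------------------------------------------------
# JSON config mirror
# ---------------------------------------------------------------------------

def _unit_from_dict(d: dict) -> UnitSimParams:
    evoked = {tuple(k.split(":")): v
              for k, v in d.get("evoked_gain", {}).items()}
    return UnitSimParams(
        unit_id=d["unit_id"],
        baseline_rate_hz=dict(d["baseline_rate_hz"]),
        evoked_gain={(s, c): float(g) for (s, c), g in evoked.items()},
        adaptation_floor=d.get("adaptation_floor", 1.0),
        adaptation_tau_trials=d.get("adaptation_tau_trials", 10.0),
        offset_gain=dict(d.get("offset_gain", {})),
        waveform_width_ms=d.get("waveform_width_ms", 0.6),
        waveform_sampling_hz=d.get("waveform_sampling_hz", 30000.0),
        unit_class=d.get("unit_class"),
        refractory_s=d.get("refractory_s", 0.0))


def _unit_to_dict(u: UnitSimParams) -> dict:
    return {
        "unit_id": u.unit_id,
        "baseline_rate_hz": u.baseline_rate_hz,
        "evoked_gain": {f"{s}:{c}": g for (s, c), g in u.evoked_gain.items()},
        "adaptation_floor": u.adaptation_floor,
        "adaptation_tau_trials": u.adaptation_tau_trials,
        "offset_gain": u.offset_gain,
        "waveform_width_ms": u.waveform_width_ms,
        "waveform_sampling_hz": u.waveform_sampling_hz,
        "unit_class": u.unit_class,
        "refractory_s": u.refractory_s,
    }


def config_from_json(path) -> SessionSimConfig:
    with open(path) as fh:
        d = json.load(fh)
    lfp = None
    if d.get("lfp") is not None:
        lf = dict(d["lfp"])
        lf["band_effects"] = [tuple(b) for b in lf.get("band_effects", [])]
        lfp = LfpSimParams(**lf)
    return SessionSimConfig(
        n_trials_per_stimulus=d.get("n_trials_per_stimulus", 25),
        stimulus_duration_s=d.get("stimulus_duration_s", 2.0),
        motifs_per_song=d.get("motifs_per_song", 2),
        inter_trial_interval_s=d.get("inter_trial_interval_s", 5.0),
        contexts=tuple(d.get("contexts", ("solitary", "social"))),
        stimuli=tuple(d.get("stimuli", STIMULI)),
        units=[_unit_from_dict(u) for u in d.get("units", [])],
        lfp=lfp, seed=d.get("seed", 0),
        lead_in_s=d.get("lead_in_s", 5.0))


def config_to_json(config: SessionSimConfig, path) -> None:
    d = {
        "n_trials_per_stimulus": config.n_trials_per_stimulus,
        "stimulus_duration_s": config.stimulus_duration_s,
        "motifs_per_song": config.motifs_per_song,
        "inter_trial_interval_s": config.inter_trial_interval_s,
        "contexts": list(config.contexts),
        "stimuli": list(config.stimuli),
        "units": [_unit_to_dict(u) for u in config.units],
        "lfp": None,
        "seed": config.seed,
        "lead_in_s": config.lead_in_s,
    }
    if config.lfp is not None:
        d["lfp"] = {
            "n_channels": config.lfp.n_channels,
            "sampling_rate_hz": config.lfp.sampling_rate_hz,
            "noise_spectrum_exponent": config.lfp.noise_spectrum_exponent,
            "line_hz": config.lfp.line_hz,
            "line_amplitude": config.lfp.line_amplitude,
            "band_effects": [list(b) for b in config.lfp.band_effects],
            "band_base_amplitude": config.lfp.band_base_amplitude,
        }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# convenience populations (used by tests and the demo pipeline)
# ---------------------------------------------------------------------------

def make_population(n_units: int, seed: int,
                    solitary_bos_gain: float = 3.0,
                    solitary_other_gain: float = 1.5,
                    social_gain_contrast: float = 0.5,
                    social_baseline_factor: float = 1.3,
                    social_baseline_sigma: float = 0.8,
                    baseline_hz: float = 6.0,
                    offset_gain: float = 1.5,
                    adaptation_floor: float = 1.0,
                    bs_fraction: float = 0.7) -> list[UnitSimParams]:
    """A population emulating the solitary-vs-social effect structure.

    Solitary units prefer BOS (``solitary_bos_gain`` vs
    ``solitary_other_gain``); in the social context the evoked increment of
    every gain is scaled by ``social_gain_contrast`` (compressed
    selectivity) and the baseline is multiplied by a per-unit lognormal
    factor with mean ``social_baseline_factor`` — raised on average but
    heterogeneous across units, so population baseline comparisons stay
    inconclusive while evoked statistics drop.
    """
    rng = np.random.default_rng([seed, 0x5e551])
    units = []
    for i in range(n_units):
        base = float(baseline_hz * rng.lognormal(0.0, 0.35))
        sigma = social_baseline_sigma
        mu = np.log(social_baseline_factor) - sigma ** 2 / 2.0
        social_mult = float(rng.lognormal(mu, sigma))
        width = float(rng.uniform(0.45, 0.8) if rng.uniform() < bs_fraction
                      else rng.uniform(0.2, 0.41))
        evoked = {}
        for stim in STIMULI:
            g_sol = solitary_bos_gain if stim == "BOS" else solitary_other_gain
            evoked[(stim, "solitary")] = g_sol
            evoked[(stim, "social")] = 1.0 + (g_sol - 1.0) * social_gain_contrast
        units.append(UnitSimParams(
            unit_id=f"u{i:03d}",
            baseline_rate_hz={"solitary": base, "social": base * social_mult},
            evoked_gain=evoked,
            adaptation_floor=adaptation_floor,
            adaptation_tau_trials=10.0,
            offset_gain={"solitary": offset_gain, "social": offset_gain},
            waveform_width_ms=width))
    return units
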