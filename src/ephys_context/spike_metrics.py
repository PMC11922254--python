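"""Per-unit spike-derived statistics.

Implements the trial-paired response quantities used throughout the
analysis: baseline-normalized Z, response strength (RS), d' selectivity,
stimulus-specific adaptation (SSA) ratio, offset responses, responsiveness
testing, and broad/narrow-spiking waveform classification.

Conventions
-----------
* Every rate is spikes/s over a half-open window ``[start, end)``.
* For song stimuli each motif contributes one evoked rate ``FR_i`` paired
  with its trial's baseline ``BLFR_i``; WN carries a single motif bound
  spanning the whole stimulus, so it contributes one pair per trial.
* Variances and covariances use the N-1 (sample) denominator.
* Degenerate 0/0 statistics return ``None`` ("undefined"), never a silent
  NaN; callers count and exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .session_model import SpikeTrain, StimulusEpoch, Session, Waveform

BS_NS_THRESHOLD_MS = 0.43
SSA_THRESHOLD = 0.6
RESPONSIVE_ALPHA = 0.05

#: playback baseline: 1 s window starting 2 s before onset (1 s buffer)
BASELINE_OFFSET_S = 2.0
BASELINE_WINDOW_S = 1.0
#: vocal-bout baseline buffer between bout edge and baseline window
VOCAL_BUFFER_S = 1.5
#: offset response window after the last motif
OFFSET_WINDOW_S = 1.0


class WaveformShapeError(ValueError):
    """Waveform lacks the trough-then-peak structure the width needs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialResponseSeries:
    """Paired evoked/baseline rates for one unit x stimulus x context.

    ``presentation_index[i]`` is the 0-based presentation number of the trial
    that produced pair ``i`` (several motif pairs may share a presentation).
    """

    unit_id: str
    stimulus: str
    context: str
    fr_hz: np.ndarray
    blfr_hz: np.ndarray
    presentation_index: np.ndarray

    def __post_init__(self) -> None:
        self.fr_hz = np.asarray(self.fr_hz, dtype=float)
        self.blfr_hz = np.asarray(self.blfr_hz, dtype=float)
        self.presentation_index = np.asarray(self.presentation_index, int)
        if not (len(self.fr_hz) == len(self.blfr_hz)
                == len(self.presentation_index)):
            raise ValueError("fr, blfr and presentation_index must pair up")
        if len(self.fr_hz) == 0:
            raise ValueError("a response series needs at least one pair")

    def __len__(self) -> int:
        return len(self.fr_hz)

    def per_presentation_fr(self) -> np.ndarray:
        """Mean FR per presentation, in presentation order."""
        order = np.unique(self.presentation_index)
        return np.asarray([self.fr_hz[self.presentation_index == k].mean()
                           for k in order])

    @property
    def n_presentations(self) -> int:
        return len(np.unique(self.presentation_index))


@dataclass
class StimulusContextMetrics:
    n_trials: int
    mean_fr_hz: Optional[float]
    mean_blfr_hz: Optional[float]
    z: Optional[float]
    rs: Optional[float]
    ssa_ratio: Optional[float]
    offset_ratio: Optional[float]
    offset_z: Optional[float]


@dataclass
class UnitMetrics:
    unit_id: str
    unit_class: Optional[str]
    responsive: bool
    per_stimulus: dict[tuple[str, str], StimulusContextMetrics] = \
        field(default_factory=dict)
    #: (stim_a, stim_b, context) -> d'
    d_prime: dict[tuple[str, str, str], Optional[float]] = \
        field(default_factory=dict)

    def max_ssa(self) -> Optional[float]:
        vals = [sc.ssa_ratio for sc in self.per_stimulus.values()
                if sc.ssa_ratio is not None]
        return max(vals) if vals else None


# ---------------------------------------------------------------------------
# waveform classification
# ---------------------------------------------------------------------------

def peak_to_peak_width(waveform: Waveform) -> float:
    """Trough-to-subsequent-peak interval of the mean waveform, in ms.

    The trough is the global minimum (required negative); the peak is the
    largest sample after it (required positive).  Anything else — a single
    lobe, or a waveform ending on its trough — raises
    :class:`WaveformShapeError`.
    """
    samples = waveform.samples
    trough = int(np.argmin(samples))
    if samples[trough] >= 0:
        raise WaveformShapeError(
            f"unit {waveform.unit_id}: no negative trough")
    if trough == len(samples) - 1:
        raise WaveformShapeError(
            f"unit {waveform.unit_id}: trough at final sample, no later peak")
    after = samples[trough + 1:]
    peak = trough + 1 + int(np.argmax(after))
    if samples[peak] <= 0:
        raise WaveformShapeError(
            f"unit {waveform.unit_id}: no positive peak after the trough")
    return (peak - trough) / waveform.sampling_rate_hz * 1e3


def classify_unit(width_ms: float,
                  threshold_ms: float = BS_NS_THRESHOLD_MS) -> str:
    """Broad- vs narrow-spiking from trough-to-peak width.

    BS strictly above threshold; the boundary case goes to NS.
    """
    if width_ms <= 0:
        raise ValueError("width must be positive")
    return "BS" if width_ms > threshold_ms else "NS"


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def motif_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Firing rate over the half-open window ``[start, end)``."""
    start, end = window
    if not end > start:
        raise ValueError(f"zero-length or inverted window ({start}, {end})")
    return train.count_in(start, end) / (end - start)


def baseline_rate_playback(train: SpikeTrain, epoch: StimulusEpoch) -> float:
    """Baseline rate: 1 s window ending 1 s before playback onset."""
    start = epoch.onset_s - BASELINE_OFFSET_S
    if start < 0:
        raise ValueError(
            f"trial {epoch.trial_id}: baseline window starts before the "
            "session")
    return motif_rate(train, (start, start + BASELINE_WINDOW_S))


def baseline_rate_vocal(train: SpikeTrain, bout: Sequence[StimulusEpoch],
                        window_s: float = BASELINE_WINDOW_S) -> float:
    """Baseline around a singing bout: rate pooled over two windows, one
    ending 1.5 s before the first motif and one starting 1.5 s after the
    last motif."""
    if not bout:
        raise ValueError("bout must contain at least one epoch")
    ordered = sorted(bout, key=lambda e: e.onset_s)
    first = ordered[0].motif_bounds[0][0]
    last = ordered[-1].motif_bounds[-1][1]
    pre = (first - VOCAL_BUFFER_S - window_s, first - VOCAL_BUFFER_S)
    post = (last + VOCAL_BUFFER_S, last + VOCAL_BUFFER_S + window_s)
    if pre[0] < 0 or post[1] > train.session_duration_s:
        raise ValueError("vocal baseline windows fall outside the session")
    count = train.count_in(*pre) + train.count_in(*post)
    return count / (2 * window_s)


# ---------------------------------------------------------------------------
# paired-series statistics
# ---------------------------------------------------------------------------

def _paired_moments(fr: np.ndarray, blfr: np.ndarray
                    ) -> tuple[float, float, float, float, float]:
    mean_fr = float(np.mean(fr))
    mean_bl = float(np.mean(blfr))
    var_fr = float(np.var(fr, ddof=1))
    var_bl = float(np.var(blfr, ddof=1))
    cov = float(np.cov(fr, blfr, ddof=1)[0, 1])
    return mean_fr, mean_bl, var_fr, var_bl, cov


def z_score(series: TrialResponseSeries,
            sqrt_denominator: bool = True) -> Optional[float]:
    """Baseline-normalized evoked response.

    ``(mean FR - mean BLFR) / sqrt(var FR + var BLFR - 2 cov(FR, BLFR))``
    over paired presentations.  ``sqrt_denominator=False`` reproduces the
    formula exactly as typeset (no square root) for replication runs.
    Returns 0.0 for an exact 0/0 and ``None`` (undefined) when only the
    denominator vanishes.
    """
    if len(series) < 2:
        raise ValueError("z_score needs at least two paired presentations")
    mean_fr, mean_bl, var_fr, var_bl, cov = _paired_moments(
        series.fr_hz, series.blfr_hz)
    numerator = mean_fr - mean_bl
    denom_sq = var_fr + var_bl - 2.0 * cov
    denom_sq = max(denom_sq, 0.0)          # guard tiny negative rounding
    if denom_sq == 0.0:
        return 0.0 if numerator == 0.0 else None
    denom = math.sqrt(denom_sq) if sqrt_denominator else denom_sq
    return numerator / denom


def response_strength(series: TrialResponseSeries) -> float:
    """RS: mean paired difference FR_i - BLFR_i (Hz)."""
    return float(np.mean(series.fr_hz - series.blfr_hz))


def d_prime(series_a: TrialResponseSeries, series_b: TrialResponseSeries,
            sqrt_denominator: bool = True) -> Optional[float]:
    """Selectivity between two stimuli:
    ``2 (RS_A - RS_B) / sqrt(var_A + var_B)`` where the variances are of the
    per-presentation paired differences.  Antisymmetric; zero on the
    diagonal; undefined (``None``) when both variances vanish but the
    response strengths differ."""
    if len(series_a) < 2 or len(series_b) < 2:
        raise ValueError("d_prime needs >= 2 presentations per series")
    diffs_a = series_a.fr_hz - series_a.blfr_hz
    diffs_b = series_b.fr_hz - series_b.blfr_hz
    rs_a, rs_b = float(diffs_a.mean()), float(diffs_b.mean())
    var_a = float(np.var(diffs_a, ddof=1))
    var_b = float(np.var(diffs_b, ddof=1))
    numerator = 2.0 * (rs_a - rs_b)
    denom_sq = var_a + var_b
    if denom_sq == 0.0:
        return 0.0 if numerator == 0.0 else None
    denom = math.sqrt(denom_sq) if sqrt_denominator else denom_sq
    return numerator / denom


def ssa_ratio(series: TrialResponseSeries) -> Optional[float]:
    """Stimulus-specific adaptation: mean of the last five presentation
    rates over the mean of the first five.

    Ratios below the 0.6 threshold mark strongly adapting units.  Needs at
    least 10 presentations so the two windows cannot overlap; an all-silent
    start (first-five mean of zero) is undefined.
    """
    per_pres = series.per_presentation_fr()
    if len(per_pres) < 10:
        raise ValueError(
            f"ssa_ratio needs >= 10 presentations, got {len(per_pres)}")
    first = float(per_pres[:5].mean())
    last = float(per_pres[-5:].mean())
    if first == 0.0:
        return None
    return last / first


def offset_rate(train: SpikeTrain, last_motif_end_s: float) -> float:
    """Rate over the 1 s window following the last motif."""
    return motif_rate(train,
                      (last_motif_end_s, last_motif_end_s + OFFSET_WINDOW_S))


def offset_ratio(train: SpikeTrain, last_motif_end_s: float,
                 blfr_hz: float) -> Optional[float]:
    """Offset response normalized by baseline: FR(1 s after last motif) / BLFR.

    Undefined when the baseline is zero.
    """
    if blfr_hz < 0:
        raise ValueError("baseline rate cannot be negative")
    if blfr_hz == 0.0:
        return None
    return offset_rate(train, last_motif_end_s) / blfr_hz


def offset_z(series: TrialResponseSeries,
             sqrt_denominator: bool = True) -> Optional[float]:
    """Z computed on per-presentation offset-window rates paired with their
    trial baselines (same formula and degenerate handling as
    :func:`z_score`)."""
    return z_score(series, sqrt_denominator=sqrt_denominator)


def is_responsive(series: TrialResponseSeries,
                  alpha: float = RESPONSIVE_ALPHA) -> bool:
    """Paired two-tailed t-test of FR vs BLFR pooled over all playbacks.

    All-zero differences (a unit that never deviates from baseline) are
    non-responsive by definition.
    """
    if len(series) < 2:
        raise ValueError("responsiveness test needs >= 2 pairs")
    diffs = series.fr_hz - series.blfr_hz
    if np.all(diffs == 0.0):
        return False
    result = stats.ttest_rel(series.fr_hz, series.blfr_hz)
    return bool(result.pvalue < alpha)


def select_analysis_units(units: Sequence[UnitMetrics],
                          ssa_threshold: float = SSA_THRESHOLD
                          ) -> list[UnitMetrics]:
    """Keep units that are responsive AND non-adapting (SSA ratio above
    threshold) for at least one stimulus."""
    kept = []
    for m in units:
        max_ssa = m.max_ssa()
        if m.responsive and max_ssa is not None and max_ssa > ssa_threshold:
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# series construction from a session
# ---------------------------------------------------------------------------

def _playback_epochs(epochs: Sequence[StimulusEpoch], stimulus: str,
                     context: str) -> list[StimulusEpoch]:
    return sorted((e for e in epochs
                   if e.stimulus == stimulus and e.context == context
                   and e.source == "playback"),
                  key=lambda e: e.onset_s)


def build_response_series(train: SpikeTrain,
                          epochs: Sequence[StimulusEpoch],
                          stimulus: str, context: str
                          ) -> Optional[TrialResponseSeries]:
    """Motif-level evoked rates paired with trial baselines.

    Returns ``None`` when the session holds no matching playback epochs.
    """
    selected = _playback_epochs(epochs, stimulus, context)
    if not selected:
        return None
    fr, blfr, idx = [], [], []
    for k, epoch in enumerate(selected):
        baseline = baseline_rate_playback(train, epoch)
        for bound in epoch.motif_bounds:
            fr.append(motif_rate(train, bound))
            blfr.append(baseline)
            idx.append(k)
    return TrialResponseSeries(train.unit_id, stimulus, context,
                               np.asarray(fr), np.asarray(blfr),
                               np.asarray(idx))


def build_offset_series(train: SpikeTrain,
                        epochs: Sequence[StimulusEpoch],
                        stimulus: str, context: str
                        ) -> Optional[TrialResponseSeries]:
    """Per-trial offset-window rates paired with trial baselines."""
    selected = _playback_epochs(epochs, stimulus, context)
    if not selected:
        return None
    fr, blfr, idx = [], [], []
    for k, epoch in enumerate(selected):
        fr.append(offset_rate(train, epoch.last_motif_end_s))
        blfr.append(baseline_rate_playback(train, epoch))
        idx.append(k)
    return TrialResponseSeries(train.unit_id, stimulus, context,
                               np.asarray(fr), np.asarray(blfr),
                               np.asarray(idx))


def pooled_series(series_list: Sequence[TrialResponseSeries]
                  ) -> TrialResponseSeries:
    """Concatenate series across stimuli/contexts for the pooled
    responsiveness test (presentation indices are re-enumerated)."""
    if not series_list:
        raise ValueError("nothing to pool")
    fr = np.concatenate([s.fr_hz for s in series_list])
    blfr = np.concatenate([s.blfr_hz for s in series_list])
    idx = np.arange(len(fr))
    first = series_list[0]
    return TrialResponseSeries(first.unit_id, "pooled", "pooled",
                               fr, blfr, idx)


def match_playback_trials(playback_epochs: Sequence[StimulusEpoch],
                          n_motifs: int, seed: int) -> list[StimulusEpoch]:
    """Seeded uniform subsample of playback trials down to the number of
    sung motifs, used to match variance between singing and playback."""
    if n_motifs >= len(playback_epochs):
        return list(playback_epochs)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(playback_epochs), size=n_motifs, replace=False)
    return [playback_epochs[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_unit_metrics(session: Session,
                         alpha: float = RESPONSIVE_ALPHA,
                         sqrt_denominator: bool = True,
                         exclusion_log: Optional[dict] = None
                         ) -> list[UnitMetrics]:
    """All per-unit metrics for every stimulus x context present.

    ``exclusion_log`` (if given) accumulates counts of undefined statistics
    and skipped combinations.
    """
    log = exclusion_log if exclusion_log is not None else {}
    log.setdefault("undefined_statistics", 0)
    log.setdefault("short_series_skipped", 0)

    combos = sorted({(e.stimulus, e.context) for e in session.epochs
                     if e.source == "playback"})
    out = []
    for train in session.spike_trains:
        waveform = session.waveform(train.unit_id)
        unit_class = None
        if waveform is not None:
            unit_class = classify_unit(peak_to_peak_width(waveform))

        series_by_combo = {}
        offset_by_combo = {}
        for stimulus, context in combos:
            s = build_response_series(train, session.epochs, stimulus, context)
            if s is not None:
                series_by_combo[(stimulus, context)] = s
            o = build_offset_series(train, session.epochs, stimulus, context)
            if o is not None:
                offset_by_combo[(stimulus, context)] = o

        responsive = False
        if series_by_combo:
            pooled = pooled_series(list(series_by_combo.values()))
            if len(pooled) >= 2:
                responsive = is_responsive(pooled, alpha=alpha)

        metrics = UnitMetrics(unit_id=train.unit_id, unit_class=unit_class,
                              responsive=responsive)
        for combo, series in series_by_combo.items():
            offset_series = offset_by_combo.get(combo)
            sc = _stimulus_context_metrics(
                series, offset_series, sqrt_denominator, log)
            metrics.per_stimulus[combo] = sc

        # d' matrix per context over the stimuli present in that context
        contexts = sorted({c for (_, c) in series_by_combo})
        for context in contexts:
            stims = sorted({s for (s, c) in series_by_combo if c == context})
            for a in stims:
                for b in stims:
                    sa = series_by_combo[(a, context)]
                    sb = series_by_combo[(b, context)]
                    if len(sa) < 2 or len(sb) < 2:
                        log["short_series_skipped"] += 1
                        continue
                    if a == b:
                        metrics.d_prime[(a, b, context)] = 0.0
                        continue
                    val = d_prime(sa, sb, sqrt_denominator=sqrt_denominator)
                    if val is None:
                        log["undefined_statistics"] += 1
                    metrics.d_prime[(a, b, context)] = val
        out.append(metrics)
    return out


def _stimulus_context_metrics(series: TrialResponseSeries,
                              offset_series: Optional[TrialResponseSeries],
                              sqrt_denominator: bool,
                              log: dict) -> StimulusContextMetrics:
    n_trials = series.n_presentations
    mean_fr = float(series.fr_hz.mean())
    mean_blfr = float(series.blfr_hz.mean())

    z = rs = ssa = None
    if len(series) >= 2:
        z = z_score(series, sqrt_denominator=sqrt_denominator)
        if z is None:
            log["undefined_statistics"] += 1
        rs = response_strength(series)
    else:
        log["short_series_skipped"] += 1
    if n_trials >= 10:
        ssa = ssa_ratio(series)
        if ssa is None:
            log["undefined_statistics"] += 1

    off_ratio = off_z = None
    if offset_series is not None:
        # ratio of means: mean offset-window rate over mean baseline rate
        mean_off = float(offset_series.fr_hz.mean())
        mean_bl = float(offset_series.blfr_hz.mean())
        if mean_bl > 0:
            off_ratio = mean_off / mean_bl
        else:
            log["undefined_statistics"] += 1
        if len(offset_series) >= 2:
            off_z = offset_z(offset_series, sqrt_denominator=sqrt_denominator)
            if off_z is None:
                log["undefined_statistics"] += 1
    return StimulusContextMetrics(
        n_trials=n_trials, mean_fr_hz=mean_fr, mean_blfr_hz=mean_blfr,
        z=z, rs=rs, ssa_ratio=ssa, offset_ratio=off_ratio, offset_z=off_z)
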