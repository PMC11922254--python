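"""Domain types for recording sessions and their on-disk formats.

A session directory holds flat, language-agnostic files:

* ``epochs.csv``    — one row per stimulus/vocalization trial
* ``spikes.csv``    — long-form (unit_id, spike_time_s) event table
* ``waveforms.csv`` — one row per unit mean waveform
* ``lfp.bin``       — little-endian float32, channel-major
* ``lfp.json``      — sidecar: sampling rate, channel names, n_samples
* ``session.json``  — session id, duration, free-form metadata

All times are in seconds, session-relative, and every interval is half-open
``[start, end)`` so boundary events are never double-counted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

STIMULI = ("BOS", "BOS_REV", "CON", "WN")
CONTEXTS = ("solitary", "social", "directed")
SOURCES = ("playback", "vocalization")

#: absolute tolerance used when validating interval geometry from text files
_EPS = 1e-9


class SessionFormatError(ValueError):
    """A session file violates the on-disk contract (bad label, bad row)."""

    def __init__(self, message: str, path: Optional[str] = None,
                 line: Optional[int] = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}"
            where += f", line {line}]" if line is not None else "]"
        super().__init__(message + where)


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusEpoch:
    """One playback or singing trial with its motif sub-intervals."""

    trial_id: int
    stimulus: str
    context: str
    onset_s: float
    offset_s: float
    motif_bounds: list[tuple[float, float]]
    source: str = "playback"

    def __post_init__(self) -> None:
        if self.stimulus not in STIMULI:
            raise ValidationError(f"unknown stimulus label {self.stimulus!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context label {self.context!r}")
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source label {self.source!r}")
        if not self.onset_s < self.offset_s:
            raise ValidationError(
                f"trial {self.trial_id}: onset {self.onset_s} must precede "
                f"offset {self.offset_s}")
        prev_end = self.onset_s - _EPS
        for start, end in self.motif_bounds:
            if start >= end:
                raise ValidationError(
                    f"trial {self.trial_id}: empty motif bound ({start}, {end})")
            if start < prev_end - _EPS:
                raise ValidationError(
                    f"trial {self.trial_id}: motif bounds overlap or are "
                    "unsorted")
            if start < self.onset_s - _EPS or end > self.offset_s + _EPS:
                raise ValidationError(
                    f"trial {self.trial_id}: motif bound ({start}, {end}) "
                    "outside stimulus interval")
            prev_end = end
        if self.stimulus == "WN":
            ok = (len(self.motif_bounds) == 1
                  and abs(self.motif_bounds[0][0] - self.onset_s) <= _EPS
                  and abs(self.motif_bounds[0][1] - self.offset_s) <= _EPS)
            if not ok:
                raise ValidationError(
                    f"trial {self.trial_id}: WN must carry exactly one motif "
                    "bound spanning the whole stimulus")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def last_motif_end_s(self) -> float:
        return self.motif_bounds[-1][1]


@dataclass
class SpikeTrain:
    """Sorted event times for one unit over the whole session."""

    unit_id: str
    spike_times_s: np.ndarray
    session_duration_s: float

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise ValidationError("spike times must be a 1-D sequence")
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValidationError(f"unit {self.unit_id}: times not sorted")
        if self.spike_times_s.size and (
                self.spike_times_s[0] < 0
                or self.spike_times_s[-1] > self.session_duration_s):
            raise ValidationError(
                f"unit {self.unit_id}: spike times outside "
                f"[0, {self.session_duration_s}]")

    def count_in(self, start_s: float, end_s: float) -> int:
        """Number of spikes in the half-open window ``[start_s, end_s)``."""
        lo, hi = np.searchsorted(self.spike_times_s, [start_s, end_s], "left")
        return int(hi - lo)


@dataclass
class Waveform:
    """Mean extracellular spike shape of one unit."""

    unit_id: str
    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 8:
            raise ValidationError(
                f"waveform {self.unit_id}: need >= 8 samples")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")


@dataclass
class LFPRecording:
    """Multichannel low-frequency signal, channel-major."""

    channels: list[str]
    signal: np.ndarray            # shape (n_channels, n_samples)
    sampling_rate_hz: float

    #: highest frequency any analysis in this package looks at
    MAX_ANALYSIS_HZ = 50.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel names but signal has "
                f"{self.signal.shape[0]} rows")
        if self.sampling_rate_hz <= 2 * self.MAX_ANALYSIS_HZ:
            raise ValidationError(
                "sampling rate must exceed twice the 50 Hz analysis band")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Session:
    """A full recording session: epochs, units, waveforms, optional LFP."""

    session_id: str
    epochs: list[StimulusEpoch]
    spike_trains: list[SpikeTrain]
    waveforms: list[Waveform] = field(default_factory=list)
    lfp: Optional[LFPRecording] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_non_overlapping(self.epochs)
        unit_ids = {t.unit_id for t in self.spike_trains}
        for w in self.waveforms:
            if w.unit_id not in unit_ids:
                raise ValidationError(
                    f"waveform {w.unit_id} has no matching spike train")

    @property
    def duration_s(self) -> float:
        if self.spike_trains:
            return max(t.session_duration_s for t in self.spike_trains)
        if self.epochs:
            return self.epochs[-1].offset_s
        return 0.0

    def spike_train(self, unit_id: str) -> SpikeTrain:
        for t in self.spike_trains:
            if t.unit_id == unit_id:
                return t
        raise KeyError(unit_id)

    def waveform(self, unit_id: str) -> Optional[Waveform]:
        for w in self.waveforms:
            if w.unit_id == unit_id:
                return w
        return None


def validate_non_overlapping(epochs: Sequence[StimulusEpoch]) -> None:
    """Raise :class:`ValidationError` if any two epochs overlap in time."""
    ordered = sorted(epochs, key=lambda e: e.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset_s < a.offset_s - _EPS:
            raise ValidationError(
                f"epochs {a.trial_id} and {b.trial_id} overlap "
                f"([{a.onset_s}, {a.offset_s}) vs [{b.onset_s}, {b.offset_s}))")


# ---------------------------------------------------------------------------
# epoch / spike / waveform tables
# ---------------------------------------------------------------------------

EPOCH_HEADER = ["trial_id", "stimulus", "context", "onset_s", "offset_s",
                "motif_bounds", "source"]
SPIKE_HEADER = ["unit_id", "spike_time_s"]
WAVEFORM_HEADER = ["unit_id", "sampling_rate_hz", "samples"]
METRICS_HEADER = ["unit_id", "unit_class", "stimulus", "context", "n_trials",
                  "mean_fr_hz", "mean_blfr_hz", "z", "rs", "ssa_ratio",
                  "offset_ratio", "offset_z", "responsive"]


def _format_motifs(bounds: Iterable[tuple[float, float]]) -> str:
    return ";".join(f"{s!r}:{e!r}" for s, e in bounds)


def _parse_motifs(text: str, path: str, line: int) -> list[tuple[float, float]]:
    bounds = []
    for chunk in text.split(";"):
        if not chunk:
            continue
        try:
            s, e = chunk.split(":")
            bounds.append((float(s), float(e)))
        except ValueError:
            raise SessionFormatError(
                f"bad motif bound {chunk!r}", path, line) from None
    return bounds


def read_epoch_table(path) -> list[StimulusEpoch]:
    """Read ``epochs.csv``; epochs are returned sorted by onset.

    Unknown stimulus/context/source labels and malformed rows raise
    :class:`SessionFormatError` carrying the 1-based line number; overlapping
    epochs raise :class:`ValidationError`.
    """
    path = str(path)
    epochs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != EPOCH_HEADER:
            raise SessionFormatError(
                f"expected header {EPOCH_HEADER}, got {reader.fieldnames}",
                path, 1)
        for row in reader:
            line = reader.line_num
            try:
                epoch = StimulusEpoch(
                    trial_id=int(row["trial_id"]),
                    stimulus=row["stimulus"],
                    context=row["context"],
                    onset_s=float(row["onset_s"]),
                    offset_s=float(row["offset_s"]),
                    motif_bounds=_parse_motifs(row["motif_bounds"], path, line),
                    source=row["source"],
                )
            except ValidationError as err:
                raise SessionFormatError(str(err), path, line) from None
            except (TypeError, ValueError, KeyError) as err:
                raise SessionFormatError(f"bad row: {err}", path, line) from None
            epochs.append(epoch)
    epochs.sort(key=lambda e: e.onset_s)
    validate_non_overlapping(epochs)
    return epochs


def write_epoch_table(epochs: Sequence[StimulusEpoch], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPOCH_HEADER)
        for e in sorted(epochs, key=lambda x: x.onset_s):
            writer.writerow([e.trial_id, e.stimulus, e.context,
                             repr(e.onset_s), repr(e.offset_s),
                             _format_motifs(e.motif_bounds), e.source])


def read_spike_table(path, session_duration_s: Optional[float] = None
                     ) -> list[SpikeTrain]:
    """Read ``spikes.csv`` into one sorted :class:`SpikeTrain` per unit.

    When ``session_duration_s`` is not given it defaults to the latest spike
    time in the file.
    """
    path = str(path)
    times: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SPIKE_HEADER:
            raise SessionFormatError(
                f"expected header {SPIKE_HEADER}, got {reader.fieldnames}",
                path, 1)
        for row in reader:
            line = reader.line_num
            try:
                t = float(row["spike_time_s"])
            except (TypeError, ValueError):
                raise SessionFormatError("bad spike time", path, line) from None
            if t < 0:
                raise SessionFormatError(
                    f"negative spike time {t}", path, line)
            times.setdefault(row["unit_id"], []).append(t)
    if session_duration_s is None:
        session_duration_s = max(
            (max(v) for v in times.values() if v), default=0.0)
    return [SpikeTrain(uid, np.sort(np.asarray(v)), session_duration_s)
            for uid, v in sorted(times.items())]


def write_spike_table(trains: Sequence[SpikeTrain], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPIKE_HEADER)
        for train in trains:
            for t in train.spike_times_s:
                writer.writerow([train.unit_id, repr(float(t))])


def read_waveform_table(path) -> list[Waveform]:
    path = str(path)
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != WAVEFORM_HEADER:
            raise SessionFormatError(
                f"expected header {WAVEFORM_HEADER}, got {reader.fieldnames}",
                path, 1)
        for row in reader:
            line = reader.line_num
            try:
                samples = np.asarray(
                    [float(x) for x in row["samples"].split(";") if x])
                out.append(Waveform(row["unit_id"], samples,
                                    float(row["sampling_rate_hz"])))
            except (ValidationError, TypeError, ValueError) as err:
                raise SessionFormatError(str(err), path, line) from None
    return out


def write_waveform_table(waveforms: Sequence[Waveform], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WAVEFORM_HEADER)
        for w in waveforms:
            writer.writerow([w.unit_id, repr(float(w.sampling_rate_hz)),
                             ";".join(repr(float(x)) for x in w.samples)])


# ---------------------------------------------------------------------------
# LFP binary + sidecar
# ---------------------------------------------------------------------------

def write_lfp(lfp: LFPRecording, bin_path, json_path) -> None:
    """Channel-major little-endian float32 with a JSON sidecar."""
    lfp.signal.astype("<f4").tofile(bin_path)
    with open(json_path, "w") as fh:
        json.dump({"sampling_rate_hz": lfp.sampling_rate_hz,
                   "channels": list(lfp.channels),
                   "n_samples": int(lfp.n_samples)}, fh, indent=1)


def read_lfp(bin_path, json_path) -> LFPRecording:
    with open(json_path) as fh:
        meta = json.load(fh)
    raw = np.fromfile(bin_path, dtype="<f4")
    n_ch, n_samp = len(meta["channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_samp:
        raise SessionFormatError(
            f"lfp.bin holds {raw.size} samples, sidecar promises "
            f"{n_ch}x{n_samp}", str(bin_path))
    return LFPRecording(list(meta["channels"]),
                        raw.reshape(n_ch, n_samp).astype(float),
                        float(meta["sampling_rate_hz"]))


# ---------------------------------------------------------------------------
# metrics table (round-trippable output of the metrics stage)
# ---------------------------------------------------------------------------

def _fmt_opt(x) -> str:
    return "" if x is None else repr(float(x))


def _parse_opt(text: str) -> Optional[float]:
    return None if text == "" else float(text)


def write_metrics_table(metrics, path) -> None:
    """Write one row per unit x stimulus x context (see METRICS_HEADER).

    ``metrics`` is a sequence of :class:`ephys_context.spike_metrics.UnitMetrics`.
    Undefined statistics serialize as empty cells.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METRICS_HEADER)
        for m in metrics:
            for (stimulus, context), sc in sorted(m.per_stimulus.items()):
                writer.writerow([
                    m.unit_id, m.unit_class or "", stimulus, context,
                    sc.n_trials, _fmt_opt(sc.mean_fr_hz),
                    _fmt_opt(sc.mean_blfr_hz), _fmt_opt(sc.z), _fmt_opt(sc.rs),
                    _fmt_opt(sc.ssa_ratio), _fmt_opt(sc.offset_ratio),
                    _fmt_opt(sc.offset_z), str(bool(m.responsive)),
                ])


def read_metrics_table(path):
    """Inverse of :func:`write_metrics_table` (d' lives in its own table)."""
    from .spike_metrics import StimulusContextMetrics, UnitMetrics
    path = str(path)
    units: dict[str, "UnitMetrics"] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != METRICS_HEADER:
            raise SessionFormatError(
                f"expected header {METRICS_HEADER}, got {reader.fieldnames}",
                path, 1)
        for row in reader:
            uid = row["unit_id"]
            if uid not in units:
                units[uid] = UnitMetrics(
                    unit_id=uid, unit_class=row["unit_class"] or None,
                    responsive=row["responsive"] == "True",
                    per_stimulus={}, d_prime={})
            units[uid].per_stimulus[(row["stimulus"], row["context"])] = \
                StimulusContextMetrics(
                    n_trials=int(row["n_trials"]),
                    mean_fr_hz=_parse_opt(row["mean_fr_hz"]),
                    mean_blfr_hz=_parse_opt(row["mean_blfr_hz"]),
                    z=_parse_opt(row["z"]), rs=_parse_opt(row["rs"]),
                    ssa_ratio=_parse_opt(row["ssa_ratio"]),
                    offset_ratio=_parse_opt(row["offset_ratio"]),
                    offset_z=_parse_opt(row["offset_z"]))
    return list(units.values())


DPRIME_HEADER = ["unit_id", "context", "stim_a", "stim_b", "d_prime"]


def write_dprime_table(metrics, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DPRIME_HEADER)
        for m in metrics:
            for (a, b, ctx), val in sorted(m.d_prime.items()):
                writer.writerow([m.unit_id, ctx, a, b, _fmt_opt(val)])


def read_dprime_table(path) -> dict[tuple[str, str, str, str], Optional[float]]:
    """Return ``{(unit_id, stim_a, stim_b, context): d_prime}``."""
    out: dict[tuple[str, str, str, str], Optional[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out[(row["unit_id"], row["stim_a"], row["stim_b"],
                 row["context"])] = _parse_opt(row["d_prime"])
    return out


# ---------------------------------------------------------------------------
# whole-session round trip
# ---------------------------------------------------------------------------

def write_session(session: Session, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_epoch_table(session.epochs, directory / "epochs.csv")
    write_spike_table(session.spike_trains, directory / "spikes.csv")
    write_waveform_table(session.waveforms, directory / "waveforms.csv")
    if session.lfp is not None:
        write_lfp(session.lfp, directory / "lfp.bin", directory / "lfp.json")
    with open(directory / "session.json", "w") as fh:
        json.dump({"session_id": session.session_id,
                   "duration_s": session.duration_s,
                   "metadata": session.metadata}, fh, indent=1)


def read_session(directory) -> Session:
    directory = Path(directory)
    with open(directory / "session.json") as fh:
        meta = json.load(fh)
    lfp = None
    if (directory / "lfp.bin").exists():
        lfp = read_lfp(directory / "lfp.bin", directory / "lfp.json")
    waveforms = []
    if (directory / "waveforms.csv").exists():
        waveforms = read_waveform_table(directory / "waveforms.csv")
    return Session(
        session_id=meta["session_id"],
        epochs=read_epoch_table(directory / "epochs.csv"),
        spike_trains=read_spike_table(directory / "spikes.csv",
                                      meta["duration_s"]),
        waveforms=waveforms,
        lfp=lfp,
        metadata=meta.get("metadata", {}),
    )
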