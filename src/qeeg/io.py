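"""Data model and file I/O: recordings (EDF), hypnograms and annotations (CSV).

Conventions used throughout the pipeline:

* times are seconds from recording start, intervals are half-open
  ``[onset, onset + duration)``;
* hypnograms are sequences of 30-s epoch labels over
  ``{W, N1, N2, N3, NREM}`` where the collapsed ``NREM`` label is mutually
  exclusive with the individual NREM stages within one recording;
* the standard montage is the referential 19-channel 10-20 set.

The EDF reader/writer implemented here covers the plain EDF subset the
pipeline produces (continuous signals, equal sampling rate on all channels,
1-s data records); it is not a general EDF+ implementation.
"""

from __future__ import annotations

import csv
import io as _stdio
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError, ValidationError

#: The 19 scalp electrode labels of the international 10-20 system, in the
#: canonical order used by every Recording produced by this package.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Longitudinal bipolar chain ("double banana").  The source montage must be
#: referential; each output channel is anode minus cathode.
BIPOLAR_CHAIN: tuple[tuple[str, str], ...] = (
    ("Fp1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fz", "Cz"), ("Cz", "Pz"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
)

STAGES = ("W", "N1", "N2", "N3", "NREM")
SLEEP_STAGES = ("N1", "N2", "N3", "NREM")
EVENT_TYPES = ("IED", "burst", "spindle", "background")

EPOCH_LENGTH_S = 30.0


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG signal in microvolts.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)``, microvolts.
    sampling_rate
        Sampling rate in Hz.
    channel_names
        One label per row of ``signal``.
    montage
        One of ``{"referential", "bipolar", "common_average"}``.
    recording_id
        Free-form identifier used in annotation files.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    montage: str = "referential"
    recording_id: str = "rec"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.montage not in ("referential", "bipolar", "common_average"):
            raise ValidationError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"channel {name!r} not in recording") from None


def validate_standard_channels(rec: Recording) -> None:
    """Check that ``rec`` carries the full 19-channel 10-20 set.

    Raises :class:`ValidationError` naming the first missing label.
    """
    missing = [ch for ch in CHANNELS_1020 if ch not in rec.channel_names]
    if missing:
        raise ValidationError(
            f"recording {rec.recording_id!r} is missing 10-20 channel "
            f"{missing[0]!r} ({len(missing)} missing in total)"
        )


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

@dataclass
class Hypnogram:
    """Sleep-stage labels in 30-s epochs."""

    stages: tuple[str, ...]
    epoch_length: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if self.epoch_length <= 0:
            raise ValidationError("epoch_length must be positive")
        for i, s in enumerate(self.stages):
            if s not in STAGES:
                raise ValidationError(f"epoch {i}: unknown stage {s!r}")
        has_nrem = "NREM" in self.stages
        has_split = any(s in ("N1", "N2", "N3") for s in self.stages)
        if has_nrem and has_split:
            raise ValidationError(
                "collapsed NREM label cannot be mixed with N1/N2/N3"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_durations(self) -> dict[str, float]:
        """Total seconds per stage label present in the hypnogram."""
        out: dict[str, float] = {}
        for s in self.stages:
            out[s] = out.get(s, 0.0) + self.epoch_length
        return out

    def intervals(self, stage: str | Sequence[str]) -> list[tuple[float, float]]:
        """Merged half-open ``[start, stop)`` intervals covered by ``stage``.

        ``stage`` may be a single label or a collection of labels.
        """
        wanted = {stage} if isinstance(stage, str) else set(stage)
        out: list[tuple[float, float]] = []
        for i, s in enumerate(self.stages):
            if s not in wanted:
                continue
            start = i * self.epoch_length
            stop = start + self.epoch_length
            if out and math.isclose(out[-1][1], start):
                out[-1] = (out[-1][0], stop)
            else:
                out.append((start, stop))
        return out

    def mask(self, stage: str | Sequence[str], sampling_rate: float,
             n_samples: int) -> np.ndarray:
        """Boolean per-sample mask of the epochs labeled ``stage``."""
        m = np.zeros(n_samples, dtype=bool)
        for start, stop in self.intervals(stage):
            a = int(round(start * sampling_rate))
            b = min(int(round(stop * sampling_rate)), n_samples)
            m[a:b] = True
        return m

    def stage_at(self, t: float) -> str:
        i = int(t // self.epoch_length)
        if not 0 <= i < self.n_epochs:
            raise ValidationError(f"time {t} s outside hypnogram")
        return self.stages[i]


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass
class Event:
    """A single timed, typed, channel-attributed event."""

    onset: float
    duration: float
    type: str
    channels: tuple[str, ...] = ()
    source: str = "manual"
    score: float | None = None
    freq_hz: float | None = None
    has_gamma: bool | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.type!r}")
        if self.onset < 0:
            raise ValidationError("event onset must be >= 0")
        if self.type in ("burst", "spindle", "background") and self.duration <= 0:
            raise ValidationError(f"{self.type} events need a positive duration")
        if self.source not in ("manual", "detected"):
            raise ValidationError(f"unknown event source {self.source!r}")
        if self.source == "detected" and self.score is not None and not np.isfinite(self.score):
            raise ValidationError("detected events must not carry NaN scores")
        self.channels = tuple(self.channels)

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def span(self, ied_duration: float = 0.25) -> tuple[float, float]:
        """Half-open time span; IED point events get an onset-centered span."""
        if self.type == "IED":
            half = ied_duration / 2.0
            c = self.onset + self.duration / 2.0 if self.duration > 0 else self.onset
            return (c - half, c + half)
        return (self.onset, self.offset)


@dataclass
class EventSet:
    """Ordered collection of :class:`Event` tied to one recording."""

    events: list[Event] = field(default_factory=list)
    recording_id: str = "rec"

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_type(self, *types: str) -> "EventSet":
        return EventSet([e for e in self.events if e.type in types],
                        self.recording_id)

    def sorted(self) -> "EventSet":
        return EventSet(sorted(self.events, key=lambda e: (e.onset, e.duration)),
                        self.recording_id)

    def restrict(self, intervals: Sequence[tuple[float, float]]) -> "EventSet":
        """Keep events whose onset falls inside any of the intervals."""
        kept = [e for e in self.events
                if any(a <= e.onset < b for a, b in intervals)]
        return EventSet(kept, self.recording_id)


# ---------------------------------------------------------------------------
# Annotation / hypnogram CSV
# ---------------------------------------------------------------------------

_ANNOT_FIELDS = ("recording_id", "onset_s", "duration_s", "type", "channels",
                 "source", "score", "freq_hz")


def write_annotations(events: EventSet, path: str | Path) -> None:
    """Write an EventSet as annotations CSV (documented dialect).

    Columns: ``recording_id,onset_s,duration_s,type,channels,source,score,freq_hz``
    with channel lists joined by ``;``.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ANNOT_FIELDS)
        for e in events:
            w.writerow([
                events.recording_id,
                f"{e.onset:.6f}",
                f"{e.duration:.6f}",
                e.type,
                ";".join(e.channels),
                e.source,
                "" if e.score is None else f"{e.score:.6f}",
                "" if e.freq_hz is None else f"{e.freq_hz:.4f}",
            ])


def read_annotations(path: str | Path) -> EventSet:
    """Read annotations CSV into an :class:`EventSet`.

    Accepts the headered dialect written by :func:`write_annotations` and
    headerless rows in the same column order.  Raises :class:`FormatError`
    with the offending row number on bad tokens.
    """
    path = Path(path)
    events: list[Event] = []
    rec_id = "rec"
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, skipinitialspace=True))
    if not rows:
        raise FormatError(f"{path}: empty annotations file")
    start = 0
    if rows[0] and rows[0][0].strip() == "recording_id":
        start = 1
    for i, row in enumerate(rows[start:], start=start + 1):
        if not row or all(not c.strip() for c in row):
            continue
        cells = [c.strip() for c in row]
        if len(cells) < 6:
            raise FormatError(f"{path} row {i}: expected >=6 columns, got {len(cells)}")
        cells += [""] * (len(_ANNOT_FIELDS) - len(cells))
        rec_id = cells[0] or rec_id
        try:
            onset = float(cells[1])
            duration = float(cells[2])
        except ValueError:
            raise FormatError(f"{path} row {i}: non-numeric onset/duration") from None
        etype = cells[3]
        if etype not in EVENT_TYPES:
            raise FormatError(f"{path} row {i}: unknown event type {etype!r}")
        channels = tuple(c for c in cells[4].split(";") if c)
        source = cells[5] or "manual"
        if source not in ("manual", "detected"):
            raise FormatError(f"{path} row {i}: unknown source {source!r}")
        score = float(cells[6]) if cells[6] else None
        freq = float(cells[7]) if cells[7] else None
        try:
            events.append(Event(onset, duration, etype, channels, source,
                                score, freq))
        except ValidationError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from None
    return EventSet(events, rec_id)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as ``epoch_index,stage`` CSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "stage"])
        for i, s in enumerate(hyp.stages):
            w.writerow([i, s])


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read an ``epoch_index,stage`` CSV into a validated :class:`Hypnogram`."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty hypnogram file")
    start = 1 if rows[0] and rows[0][0].strip() == "epoch_index" else 0
    stages: list[tuple[int, str]] = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise FormatError(f"{path} row {i}: expected epoch_index,stage")
        try:
            idx = int(row[0])
        except ValueError:
            raise FormatError(f"{path} row {i}: non-integer epoch index") from None
        stage = row[1].strip()
        if stage not in STAGES:
            raise FormatError(f"{path} row {i}: unknown stage {stage!r}")
        stages.append((idx, stage))
    stages.sort()
    if [i for i, _ in stages] != list(range(len(stages))):
        raise FormatError(f"{path}: epoch indices are not contiguous from 0")
    try:
        return Hypnogram(tuple(s for _, s in stages))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording to plain EDF (int16, 1-s data records).

    The number of samples per second must be integral; recordings whose
    duration is not a whole number of seconds are zero-padded to the next
    record boundary.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nch = rec.n_channels
    n_records = int(math.ceil(rec.n_samples / fs))
    sig = np.zeros((nch, n_records * fs), dtype=np.float64)
    sig[:, : rec.n_samples] = rec.signal

    pmin = np.floor(sig.min(axis=1))
    pmax = np.ceil(sig.max(axis=1))
    flat = pmax <= pmin
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((sig - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = _stdio.BytesIO()
    header.write(_pad("0", 8))
    header.write(_pad(rec.recording_id[:80], 80))
    header.write(_pad(f"montage:{rec.montage}"[:80], 80))
    header.write(_pad("01.01.00", 8))
    header.write(_pad("00.00.00", 8))
    header.write(_pad(str(256 * (1 + nch)), 8))
    header.write(_pad("", 44))
    header.write(_pad(str(n_records), 8))
    header.write(_pad("1", 8))
    header.write(_pad(str(nch), 4))
    for name in rec.channel_names:
        header.write(_pad(name[:16], 16))
    for _ in range(nch):
        header.write(_pad("", 80))
    for _ in range(nch):
        header.write(_pad("uV", 8))
    for v in pmin:
        header.write(_pad(f"{v:.0f}", 8))
    for v in pmax:
        header.write(_pad(f"{v:.0f}", 8))
    for _ in range(nch):
        header.write(_pad(str(dmin), 8))
    for _ in range(nch):
        header.write(_pad(str(dmax), 8))
    for _ in range(nch):
        header.write(_pad("", 80))
    for _ in range(nch):
        header.write(_pad(str(fs), 8))
    for _ in range(nch):
        header.write(_pad("", 32))

    with Path(path).open("wb") as fh:
        fh.write(header.getvalue())
        # data records: per record, all samples of signal 0, then signal 1, ...
        reshaped = digital.reshape(nch, n_records, fs)
        interleaved = np.transpose(reshaped, (1, 0, 2))
        fh.write(interleaved.tobytes())


def _read_field(buf: bytes, pos: int, width: int) -> tuple[str, int]:
    return buf[pos:pos + width].decode("ascii", errors="replace").strip(), pos + width


def read_edf(path: str | Path) -> Recording:
    """Read a plain EDF file into a :class:`Recording` (microvolt scale).

    Raises :class:`FormatError` on truncated or malformed files.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: file too short for an EDF header")
    pos = 0
    _, pos = _read_field(raw, pos, 8)          # version
    rec_id, pos = _read_field(raw, pos, 80)    # patient
    rec_info, pos = _read_field(raw, pos, 80)  # recording
    _, pos = _read_field(raw, pos, 8)
    _, pos = _read_field(raw, pos, 8)
    header_bytes_s, pos = _read_field(raw, pos, 8)
    _, pos = _read_field(raw, pos, 44)
    n_records_s, pos = _read_field(raw, pos, 8)
    record_dur_s, pos = _read_field(raw, pos, 8)
    nch_s, pos = _read_field(raw, pos, 4)
    try:
        header_bytes = int(header_bytes_s)
        n_records = int(n_records_s)
        record_dur = float(record_dur_s)
        nch = int(nch_s)
    except ValueError:
        raise FormatError(f"{path}: non-numeric EDF header fields") from None
    if nch <= 0 or n_records < 0 or record_dur <= 0:
        raise FormatError(f"{path}: implausible EDF header")
    if len(raw) < header_bytes or header_bytes != 256 * (1 + nch):
        raise FormatError(f"{path}: EDF header size mismatch")

    def fields(width: int) -> list[str]:
        nonlocal pos
        out = []
        for _ in range(nch):
            v, pos = _read_field(raw, pos, width)
            out.append(v)
        return out

    labels = fields(16)
    fields(80)
    fields(8)
    try:
        pmin = np.array([float(v) for v in fields(8)])
        pmax = np.array([float(v) for v in fields(8)])
        dmin = np.array([float(v) for v in fields(8)])
        dmax = np.array([float(v) for v in fields(8)])
    except ValueError:
        raise FormatError(f"{path}: non-numeric EDF signal scaling") from None
    fields(80)
    try:
        spr = [int(v) for v in fields(8)]
    except ValueError:
        raise FormatError(f"{path}: non-numeric samples-per-record") from None
    fields(32)

    if len(set(spr)) != 1:
        raise FormatError(f"{path}: mixed sampling rates are not supported")
    fs = spr[0] / record_dur
    expected = header_bytes + 2 * n_records * nch * spr[0]
    if len(raw) < expected:
        raise FormatError(f"{path}: truncated EDF data section")
    data = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    data = data.reshape(n_records, nch, spr[0]).astype(np.float64)
    gain = (pmax - pmin) / (dmax - dmin)
    sig = np.transpose(data, (1, 0, 2)).reshape(nch, -1)
    sig = (sig - dmin[:, None]) * gain[:, None] + pmin[:, None]

    montage = "referential"
    if rec_info.startswith("montage:"):
        montage = rec_info.split(":", 1)[1]
    return Recording(sig, fs, tuple(labels), montage=montage,
                     recording_id=rec_id or "rec")


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def to_montage(rec: Recording, target: str) -> Recording:
    """Re-reference a referential recording.

    ``common_average`` subtracts the instantaneous mean of all channels;
    ``bipolar`` builds the longitudinal double-banana chain.  Only the
    referential montage can be transformed (the operations are not
    invertible from derived montages).
    """
    if target == rec.montage:
        return rec
    if rec.montage != "referential":
        raise ValidationError(
            f"cannot derive {target!r} from montage {rec.montage!r}"
        )
    if target == "common_average":
        avg = rec.signal.mean(axis=0, keepdims=True)
        return replace(rec, signal=rec.signal - avg, montage="common_average")
    if target == "bipolar":
        rows = []
        names = []
        for anode, cathode in BIPOLAR_CHAIN:
            ia = rec.channel_index(anode)
            ic = rec.channel_index(cathode)
            rows.append(rec.signal[ia] - rec.signal[ic])
            names.append(f"{anode}-{cathode}")
        return Recording(np.array(rows), rec.sampling_rate, tuple(names),
                         montage="bipolar", recording_id=rec.recording_id)
    raise ValidationError(f"unknown target montage {target!r}")


def union_intervals(intervals: Iterable[tuple[float, float]]
                    ) -> list[tuple[float, float]]:
    """Union of half-open intervals, returned sorted and merged."""
    ivs = sorted((a, b) for a, b in intervals if b > a)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out
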