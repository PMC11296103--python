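"""Sleep-spindle detection in N2 by percentile thresholding.

Per channel the signal is band-passed to 10-16 Hz, squared, smoothed with
a 300-ms centered moving average, and thresholded at the 80th percentile
of the smoothed envelope over N2 samples.  Supra-threshold runs lasting
0.5-3 s become candidate spindles; detections overlapping an IED are
dropped, detections on different channels within 0.5 s are merged for
rate computation, and every spindle is classified fast (>= 12 Hz) or slow
(< 12 Hz) by its spectral peak.  The percentile threshold makes detection
invariant to rescaling the whole recording by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, ValidationError
from .io import Event, EventSet, Hypnogram, Recording

N2_LIKE = ("N2",)


@dataclass
class SpindleParams:
    band: tuple[float, float] = (10.0, 16.0)
    fast_band: tuple[float, float] = (12.0, 16.0)
    slow_band: tuple[float, float] = (10.0, 12.0)
    min_dur: float = 0.5
    max_dur: float = 3.0
    smooth_window_s: float = 0.3
    threshold_percentile: float = 80.0
    min_n2_duration: float = 60.0
    merge_gap_s: float = 0.5
    per_channel_threshold: bool = True
    #: secondary criterion: a candidate run is kept only when its envelope
    #: peak reaches ``peak_factor`` times the percentile threshold.  1/f
    #: background crosses the 80th percentile for >0.5 s often enough that
    #: start/stop thresholding alone is unusable; the two-threshold scheme
    #: (start/stop at the percentile, peak above a multiple) is standard.
    #: Both thresholds scale quadratically with amplitude, so detection
    #: stays scale-invariant.  Set to 1.0 to disable.
    peak_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.min_dur >= self.max_dur:
            raise ParameterError("min_dur must be < max_dur")
        if not (self.slow_band[0] == self.band[0]
                and self.slow_band[1] == self.fast_band[0]
                and self.fast_band[1] == self.band[1]):
            raise ParameterError("slow and fast bands must partition the band")
        if not 0 < self.threshold_percentile < 100:
            raise ParameterError("threshold_percentile must lie in (0, 100)")


@dataclass
class SpindleReport:
    rate_all: float
    rate_fast: float
    rate_slow: float
    n2_duration: float
    per_channel_rates: dict[str, float] = field(default_factory=dict)
    eligible: bool = True

    def __post_init__(self) -> None:
        if self.eligible and not np.isclose(
                self.rate_all, self.rate_fast + self.rate_slow):
            raise ValidationError("rate_all must equal rate_fast + rate_slow")


def _n2_intervals(hyp: Hypnogram) -> list[tuple[float, float]]:
    return hyp.intervals(N2_LIKE)


def smoothed_envelope(x: np.ndarray, fs: float,
                      params: SpindleParams) -> np.ndarray:
    """Squared band-passed signal under a centered moving average."""
    sos = sps.butter(4, list(params.band), btype="bandpass", fs=fs,
                     output="sos")
    bp = sps.sosfiltfilt(sos, x, axis=-1)
    m = max(int(round(params.smooth_window_s * fs)), 1)
    kernel = np.ones(m) / m
    if bp.ndim == 1:
        return np.convolve(bp ** 2, kernel, mode="same")
    return np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), -1, bp ** 2)


def dominant_frequency(segment: np.ndarray, fs: float,
                       band: tuple[float, float] = (10.0, 16.0)) -> float:
    """Spectral peak of an event segment inside ``band`` (zero-padded FFT)."""
    n = max(int(2 ** np.ceil(np.log2(max(segment.size, 8)))) * 8, 1024)
    spec = np.abs(np.fft.rfft(segment - segment.mean(), n=n)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any():
        raise ParameterError("band empty at this sampling rate")
    return float(freqs[m][np.argmax(spec[m])])


def classify_spindle(event: Event, rec: Recording,
                     params: SpindleParams | None = None) -> str:
    """``"fast"`` when the dominant frequency is >= 12 Hz, else ``"slow"``.

    The 12-Hz boundary is assigned to the fast band.
    """
    params = params or SpindleParams()
    freq = event.freq_hz
    if freq is None:
        fs = rec.sampling_rate
        a = int(round(event.onset * fs))
        b = int(round(event.offset * fs))
        ch = rec.channel_index(event.channels[0]) if event.channels else 0
        freq = dominant_frequency(rec.signal[ch, a:b], fs, params.band)
    return "fast" if freq >= params.fast_band[0] else "slow"


def detect_spindles(rec: Recording, hyp: Hypnogram,
                    params: SpindleParams | None = None) -> EventSet:
    """Detect candidate spindles per channel, restricted to N2 epochs.

    Requires the common-average montage.  Returns an empty set when the
    hypnogram carries no N2.  Each detection carries its dominant frequency
    in ``freq_hz``.
    """
    params = params or SpindleParams()
    if rec.montage != "common_average":
        raise ValidationError("spindle detection requires the common-average "
                              "montage (see to_montage)")
    n2 = [(a, min(b, rec.duration)) for a, b in _n2_intervals(hyp)
          if a < rec.duration]
    if not n2:
        return EventSet([], rec.recording_id)
    fs = rec.sampling_rate
    n2_mask = hyp.mask(N2_LIKE, fs, rec.n_samples)
    env = smoothed_envelope(rec.signal, fs, params)

    events: list[Event] = []
    if params.per_channel_threshold:
        thresholds = np.percentile(env[:, n2_mask], params.threshold_percentile,
                                   axis=1)
    else:
        thresholds = np.full(rec.n_channels,
                             np.percentile(env[:, n2_mask],
                                           params.threshold_percentile))
    # Duration is measured on a refined span: within each supra-threshold
    # run, keep the samples where the envelope reaches max(threshold,
    # run peak / 16) -- this strips elevated-background flanks dragged along
    # by strong short transients -- then shrink by half the smoothing
    # window per side, since the centered moving average widens every
    # crossing by that much.
    half = int(round(params.smooth_window_s * fs / 2.0))
    for ch in range(rec.n_channels):
        supra = (env[ch] > thresholds[ch]) & n2_mask
        padded = np.concatenate([[False], supra, [False]]).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        for a0, b0 in zip(edges[::2], edges[1::2]):
            peak = env[ch, a0:b0].max()
            if peak < params.peak_factor * thresholds[ch]:
                continue
            level = max(thresholds[ch], peak / 16.0)
            core = np.flatnonzero(env[ch, a0:b0] >= level)
            a = a0 + int(core[0]) + half
            b = a0 + int(core[-1]) + 1 - half
            dur = (b - a) / fs
            if not params.min_dur <= dur <= params.max_dur:
                continue
            onset = a / fs
            freq = dominant_frequency(rec.signal[ch, a:b], fs, params.band)
            events.append(Event(onset, dur, "spindle",
                                (rec.channel_names[ch],),
                                source="detected", score=1.0, freq_hz=freq))
    events.sort(key=lambda e: e.onset)
    return EventSet(events, rec.recording_id)


def exclude_ied_overlap(spindles: EventSet, ieds: EventSet) -> EventSet:
    """Drop spindles whose span intersects any IED (250-ms) or burst span."""
    spans = [e.span() for e in ieds if e.type in ("IED", "burst")]
    kept = [s for s in spindles
            if not any(s.onset < b and s.offset > a for a, b in spans)]
    return EventSet(kept, spindles.recording_id)


def merge_across_channels(spindles: EventSet,
                          params: SpindleParams | None = None) -> EventSet:
    """Count near-simultaneous per-channel detections once.

    Detections whose span overlaps, or starts within ``merge_gap_s`` of,
    the running merged event are pooled into it, keeping the earliest
    onset and that detection's frequency.
    """
    params = params or SpindleParams()
    merged: list[Event] = []
    for ev in sorted(spindles, key=lambda e: e.onset):
        if merged and ev.onset <= merged[-1].offset + params.merge_gap_s:
            prev = merged[-1]
            merged[-1] = Event(prev.onset,
                               max(prev.duration, ev.offset - prev.onset),
                               "spindle",
                               tuple(dict.fromkeys(prev.channels + ev.channels)),
                               source="detected", score=prev.score,
                               freq_hz=prev.freq_hz)
        else:
            merged.append(ev)
    return EventSet(merged, spindles.recording_id)


def spindle_rates(spindles: EventSet, hyp: Hypnogram,
                  params: SpindleParams | None = None,
                  channel_names: tuple[str, ...] = (),
                  already_merged: bool = False) -> SpindleReport:
    """Spindle counts per minute of N2, overall and per band.

    Recordings with less than ``min_n2_duration`` of N2 are flagged
    ineligible and report no rates.  Per-channel rates (for topography)
    count every channel a merged event was seen on.
    """
    params = params or SpindleParams()
    n2_s = sum(b - a for a, b in _n2_intervals(hyp))
    if n2_s < params.min_n2_duration:
        return SpindleReport(float("nan"), float("nan"), float("nan"),
                             n2_s, {}, eligible=False)
    merged = spindles if already_merged else merge_across_channels(spindles,
                                                                   params)
    minutes = n2_s / 60.0
    n_fast = sum(1 for e in merged
                 if (e.freq_hz or 0.0) >= params.fast_band[0])
    n_slow = len(merged) - n_fast
    per_channel: dict[str, float] = {c: 0.0 for c in channel_names}
    for e in merged:
        for c in e.channels:
            per_channel[c] = per_channel.get(c, 0.0) + 1.0 / minutes
    return SpindleReport(len(merged) / minutes, n_fast / minutes,
                         n_slow / minutes, n2_s, per_channel)
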