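"""Endpoints derived from an IED EventSet: burden, channel counts, gamma.

The burden statistic is the percentage of analyzed EEG time covered by
epileptiform activity: every IED contributes a fixed 250-ms span and every
annotated burst its full duration.  Overlapping spans are unioned before
summation, so burden is a coverage measure bounded by 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, SelectionError, ValidationError
from .io import EventSet, Hypnogram, Recording, SLEEP_STAGES, union_intervals

IED_EVENT_DURATION_S = 0.25


@dataclass
class BurdenReport:
    burden_percent: float
    n_ieds: int
    n_bursts: int
    analyzed_state: str
    analyzed_duration: float
    ied_event_duration: float = IED_EVENT_DURATION_S

    def __post_init__(self) -> None:
        if not 0.0 <= self.burden_percent <= 100.0 + 1e-9:
            raise ValidationError("burden must lie in [0, 100] %")
        if self.analyzed_duration <= 0:
            raise ValidationError("analyzed_duration must be positive")


@dataclass
class GammaParams:
    """Gamma-precursor test: band, look-back window and presence criterion."""

    band: tuple[float, float] = (30.0, 70.0)
    precursor_window_s: float = 0.2
    presence_z: float = 2.0          # RMS >= mean + z * SD of background RMS
    n_background_windows: int = 50

    def validate(self, sampling_rate: float) -> None:
        if self.band[1] >= sampling_rate / 2:
            raise ParameterError("gamma band exceeds the Nyquist frequency")
        if self.band[0] <= 0 or self.band[0] >= self.band[1]:
            raise ParameterError("invalid gamma band")


# ---------------------------------------------------------------------------
# vigilance-state selection
# ---------------------------------------------------------------------------

def select_common_state(hyp_pre: Hypnogram, hyp_post: Hypnogram) -> str:
    """State shared by both hypnograms maximizing the minimum duration.

    Any sleep state takes precedence over Wake regardless of duration
    (sleep recordings carry more interictal activity and are preferred for
    the comparison).
    """
    d_pre = hyp_pre.stage_durations()
    d_post = hyp_post.stage_durations()
    common = set(d_pre) & set(d_post)
    if not common:
        raise SelectionError("hypnograms share no vigilance state")
    sleep = [s for s in common if s in SLEEP_STAGES]
    candidates = sleep if sleep else sorted(common)
    return max(sorted(candidates), key=lambda s: min(d_pre[s], d_post[s]))


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def event_spans(events: EventSet,
                ied_duration: float = IED_EVENT_DURATION_S
                ) -> list[tuple[float, float]]:
    """Unioned half-open spans of IEDs (fixed duration) and bursts."""
    spans = [e.span(ied_duration) for e in events if e.type in ("IED", "burst")]
    return union_intervals(spans)


def compute_burden(events: EventSet, total_duration: float,
                   analyzed_state: str = "all") -> BurdenReport:
    """Percentage of ``total_duration`` covered by IED/burst spans.

    ``events`` must already be restricted to the analyzed vigilance state;
    ``total_duration`` is the total duration of the analyzed segments.
    """
    if total_duration <= 0:
        raise ParameterError("total_duration must be > 0")
    ieds = events.of_type("IED")
    bursts = events.of_type("burst")
    covered = sum(b - a for a, b in event_spans(events))
    burden = min(covered / total_duration * 100.0, 100.0)
    return BurdenReport(burden, len(ieds), len(bursts), analyzed_state,
                        total_duration)


def burden_in_state(events: EventSet, hyp: Hypnogram, state: str,
                    recording_duration: float | None = None) -> BurdenReport:
    """Burden restricted to the epochs of one vigilance state."""
    intervals = hyp.intervals(state)
    if recording_duration is not None:
        intervals = [(a, min(b, recording_duration)) for a, b in intervals
                     if a < recording_duration]
    total = sum(b - a for a, b in intervals)
    if total <= 0:
        raise SelectionError(f"no {state!r} epochs to analyze")
    return compute_burden(events.restrict(intervals), total, state)


# ---------------------------------------------------------------------------
# channel involvement
# ---------------------------------------------------------------------------

def channel_involvement(events: EventSet) -> tuple[np.ndarray, float | None]:
    """Per-event channel counts and their 95th percentile summary.

    Quantiles use linear interpolation between closest ranks.  An empty
    event set yields ``(empty array, None)``.
    """
    counts = np.array([len(e.channels)
                       for e in events.of_type("IED", "burst")], dtype=float)
    if counts.size == 0:
        return counts, None
    return counts, float(np.percentile(counts, 95))


# ---------------------------------------------------------------------------
# gamma precursors
# ---------------------------------------------------------------------------

def _band_rms(sig_band: np.ndarray, fs: float, start: float, stop: float
              ) -> float | None:
    a, b = int(round(start * fs)), int(round(stop * fs))
    if a < 0 or b > sig_band.shape[-1] or b <= a:
        return None
    seg = sig_band[..., a:b]
    return float(np.sqrt(np.mean(seg ** 2)))


def gamma_proportion(rec: Recording, ied_events: EventSet,
                     params: GammaParams | None = None,
                     seed: int = 0) -> float | None:
    """Percentage of IEDs with 30-70 Hz activity just before onset.

    For each IED the maximum single-channel RMS of the band-passed signal in
    the look-back window is compared against the distribution of equal-length
    event-free background windows (presence when RMS exceeds background
    mean + ``presence_z`` SD).  Returns ``None`` when there are no IEDs.
    """
    params = params or GammaParams()
    params.validate(rec.sampling_rate)
    ieds = list(ied_events.of_type("IED"))
    if not ieds:
        return None
    fs = rec.sampling_rate
    sos = sps.butter(4, list(params.band), btype="bandpass", fs=fs,
                     output="sos")
    band = sps.sosfiltfilt(sos, rec.signal, axis=1)

    busy = union_intervals([(e.span()[0] - 0.5, e.span()[1] + 0.5)
                            for e in ied_events])
    rng = np.random.default_rng(seed)
    w = params.precursor_window_s
    bg_rms: list[float] = []
    attempts = 0
    while len(bg_rms) < params.n_background_windows and attempts < 2000:
        attempts += 1
        t = rng.uniform(0, rec.duration - w)
        if any(t < b and t + w > a for a, b in busy):
            continue
        r = _band_rms(band, fs, t, t + w)
        if r is not None:
            bg_rms.append(r)
    if len(bg_rms) < 10:
        raise SelectionError(
            "too few event-free segments to form a gamma reference distribution")
    mu, sd = float(np.mean(bg_rms)), float(np.std(bg_rms))
    crit = mu + params.presence_z * sd

    positive = 0
    counted = 0
    for ev in ieds:
        r = _band_rms(band, fs, ev.onset - w, ev.onset)
        if r is None:
            continue
        counted += 1
        if r >= crit:
            positive += 1
    if counted == 0:
        return None
    return 100.0 * positive / counted


# ---------------------------------------------------------------------------
# change score
# ---------------------------------------------------------------------------

def percent_change(pre_metric: float, post_metric: float) -> float | None:
    """100 x (post - pre) / pre; ``None`` (with a warning) when pre is 0."""
    if pre_metric == 0:
        warnings.warn("percent change undefined for a zero baseline metric")
        return None
    return 100.0 * (post_metric - pre_metric) / pre_metric
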