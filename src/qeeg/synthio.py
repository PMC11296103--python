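"""Synthetic EEG cohort generator with exact ground truth.

Produces 19-channel recordings with a 1/f background, injected
spike(-wave) discharges, multi-second spike bursts, N2-restricted spindle
oscillations with optional gamma precursors, block hypnograms, and paired
baseline/follow-up cohorts whose default calibration targets the cohort
medians the pipeline is meant to reproduce (baseline burden ~5.4% falling
to ~1.5%, fast spindle rates ~0.8 rising to ~1.5 per minute of N2).

All randomness flows through ``numpy.random.default_rng`` seeded from the
``seed`` field; a fixed seed yields bit-identical output.  Independent
substreams (background, hypnogram, focal-channel choice, each event class)
are derived from the seed so that event draws can be replayed without
re-synthesizing signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import GenerationError, ParameterError
from .io import (CHANNELS_1020, Event, EventSet, Hypnogram, Recording,
                 union_intervals)

# substream labels -> offsets mixed into the seed sequence
_STREAMS = {"background": 0, "hypnogram": 1, "focal": 2, "ied": 3,
            "burst": 4, "spindle": 5, "gamma": 6}

#: channels carrying injected spindles (fronto-centro-parietal)
SPINDLE_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")

IED_EVENT_DURATION_S = 0.25

#: the 70-ms spike is placed so its center coincides with the center of the
#: event's 250-ms analysis span (the slow wave trails behind)
_SPIKE_LEAD_S = 0.09


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass
class SynthParams:
    """Generator knobs; all rates are events per minute.

    ``spindle_rate_n2``/``spindle_freq`` drive the primary (by default fast)
    spindle population; a second, slow population is available through
    ``slow_spindle_rate_n2``/``slow_spindle_freq`` so paired cohorts can move
    fast rates while keeping slow rates flat.
    """

    sampling_rate: float = 256.0
    duration: float = 300.0
    n_channels: int = 19
    background_exponent: float = 1.0
    background_sd: float = 15.0          # microvolts, broadband
    alpha_amplitude: float = 3.0         # microvolts, 10-Hz rhythm
    ied_rate: float = 6.0
    burst_rate: float = 0.0
    burst_duration: float = 3.0
    spindle_rate_n2: float = 1.0
    spindle_freq: float = 13.0
    slow_spindle_rate_n2: float = 0.0
    slow_spindle_freq: float = 11.0
    gamma_precursor_fraction: float = 0.0
    ied_amplitude_sd: float = 8.0        # spike peak in units of background SD
    spindle_amplitude_sd: float = 2.5    # spindle peak in units of background SD
    gamma_amplitude_sd: float = 1.0      # gamma RMS in units of background SD
    n_focal_channels: int = 3
    hypnogram_fractions: tuple[tuple[str, float], ...] = (
        ("W", 0.10), ("N1", 0.10), ("N2", 0.60), ("N3", 0.20))
    collapse_nrem: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.n_channels != len(CHANNELS_1020):
            raise ParameterError("generator only supports the 19-channel 10-20 set")
        for name in ("ied_rate", "burst_rate", "spindle_rate_n2",
                     "slow_spindle_rate_n2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("spindle_freq", "slow_spindle_freq"):
            if not 10.0 <= getattr(self, name) <= 16.0:
                raise ParameterError(f"{name} must lie in [10, 16] Hz")
        if not 0.0 <= self.gamma_precursor_fraction <= 1.0:
            raise ParameterError("gamma_precursor_fraction must lie in [0, 1]")
        if self.burst_duration <= 0:
            raise ParameterError("burst_duration must be > 0")
        total = sum(f for _, f in self.hypnogram_fractions)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ParameterError("hypnogram fractions must sum to 1")


@dataclass
class GroundTruth:
    """Injected events with exact timing plus the hypnogram used."""

    events: EventSet
    hypnogram: Hypnogram


def nominal_burden_percent(params: SynthParams) -> float:
    """Event-time budget of the generator: expected burden in percent."""
    per_min = params.ied_rate * IED_EVENT_DURATION_S \
        + params.burst_rate * params.burst_duration
    return per_min / 60.0 * 100.0


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def generate_hypnogram(params: SynthParams) -> Hypnogram:
    """Fixed block sequence of stages covering the recording duration."""
    n_epochs = int(math.ceil(params.duration / 30.0))
    counts = [int(round(f * n_epochs)) for _, f in params.hypnogram_fractions]
    while sum(counts) > n_epochs:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_epochs:
        counts[int(np.argmax([f for _, f in params.hypnogram_fractions]))] += 1
    stages: list[str] = []
    for (stage, _), c in zip(params.hypnogram_fractions, counts):
        stages.extend([stage] * c)
    if params.collapse_nrem:
        stages = ["NREM" if s in ("N1", "N2", "N3") else s for s in stages]
    return Hypnogram(tuple(stages))


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def generate_background(params: SynthParams) -> Recording:
    """19-channel 1/f^beta noise plus a low-amplitude 10-Hz rhythm."""
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    rng = _rng(params.seed, "background")
    white = rng.standard_normal((params.n_channels, n))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-params.background_exponent / 2.0)
    shaping[0] = 0.0
    sig = np.fft.irfft(spectrum * shaping[None, :], n=n, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sig = sig / sd * params.background_sd
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=params.n_channels)
    sig += params.alpha_amplitude * np.sin(
        2 * np.pi * 10.0 * t[None, :] + phases[:, None])
    return Recording(sig, fs, CHANNELS_1020, montage="referential",
                     recording_id=f"synth-{params.seed}")


# ---------------------------------------------------------------------------
# event templates
# ---------------------------------------------------------------------------

def ied_template(fs: float, amplitude: float, slow_wave: bool = True
                 ) -> np.ndarray:
    """Triphasic 70-ms spike, optionally followed by a 300-ms slow wave."""
    def lobe(dur: float, amp: float) -> np.ndarray:
        m = max(int(round(dur * fs)), 2)
        return amp * np.sin(np.linspace(0, np.pi, m))

    parts = [lobe(0.015, 0.3 * amplitude),
             lobe(0.025, -amplitude),
             lobe(0.030, 0.45 * amplitude)]
    if slow_wave:
        parts.append(lobe(0.300, 0.5 * amplitude))
    return np.concatenate(parts)


def spindle_template(fs: float, freq: float, duration: float,
                     amplitude: float, phase: float = 0.0) -> np.ndarray:
    """Hann-windowed sinusoid: an amplitude-modulated spindle."""
    m = int(round(duration * fs))
    t = np.arange(m) / fs
    return amplitude * np.hanning(m) * np.sin(2 * np.pi * freq * t + phase)


def _gamma_burst(rng: np.random.Generator, fs: float, duration: float,
                 rms: float) -> np.ndarray:
    m = int(round(duration * fs))
    noise = rng.standard_normal(m + 2 * int(fs))
    sos = sps.butter(4, [30.0, 70.0], btype="bandpass", fs=fs, output="sos")
    burst = sps.sosfiltfilt(sos, noise)[int(fs):int(fs) + m]
    burst *= np.hanning(m)
    cur = np.sqrt(np.mean(burst ** 2))
    return burst / cur * rms if cur > 0 else burst


# ---------------------------------------------------------------------------
# event injection
# ---------------------------------------------------------------------------

def _draw_onsets(rng: np.random.Generator, n: int, low: float, high: float,
                 occupied: list[tuple[float, float]], width: float,
                 retries: int = 500) -> list[float]:
    onsets: list[float] = []
    for _ in range(n):
        for _attempt in range(retries):
            t = rng.uniform(low, high - width)
            span = (t, t + width)
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                occupied.append(span)
                onsets.append(t)
                break
        else:
            raise GenerationError(
                "event placement retry budget exhausted; lower the rates "
                "or lengthen the recording")
    return onsets


def _n2_like_intervals(hyp: Hypnogram) -> list[tuple[float, float]]:
    labels = ("N2",) if "N2" in hyp.stages else ("NREM",)
    return hyp.intervals(labels)


def inject_events(rec: Recording, params: SynthParams,
                  hypnogram: Hypnogram | None = None
                  ) -> tuple[Recording, GroundTruth]:
    """Add IEDs, bursts, spindles (and gamma precursors) to a background.

    Returns a new Recording plus the exact ground truth.  IED events carry
    the fixed 250-ms analysis duration; spindles carry their true frequency
    in ``freq_hz``; IEDs note whether a gamma precursor was injected.
    """
    if hypnogram is None:
        hypnogram = generate_hypnogram(params)
    fs = rec.sampling_rate
    sig = rec.signal.copy()
    n = sig.shape[1]
    dur = rec.duration
    amp_ied = params.ied_amplitude_sd * params.background_sd
    amp_spin = params.spindle_amplitude_sd * params.background_sd

    focal_rng = _rng(params.seed, "focal")
    focal_idx = np.sort(focal_rng.choice(len(CHANNELS_1020),
                                         size=params.n_focal_channels,
                                         replace=False))
    focal_names = tuple(CHANNELS_1020[i] for i in focal_idx)

    occupied: list[tuple[float, float]] = []
    events: list[Event] = []

    def add_waveform(idx: np.ndarray, start: float, wave: np.ndarray) -> None:
        a = int(round(start * fs))
        b = min(a + wave.size, n)
        if b > a:
            sig[np.asarray(idx)[:, None], np.arange(a, b)[None, :]] += wave[: b - a]

    # --- IEDs ------------------------------------------------------------
    ied_rng = _rng(params.seed, "ied")
    n_ied = int(ied_rng.poisson(params.ied_rate * dur / 60.0))
    margin = 0.6   # guard band so 500-ms windows around events stay clean
    onsets = _draw_onsets(ied_rng, n_ied, margin, dur - margin, occupied, 0.5)
    template = ied_template(fs, amp_ied)
    gamma_rng = _rng(params.seed, "gamma")
    for t in sorted(onsets):
        has_gamma = bool(gamma_rng.uniform() < params.gamma_precursor_fraction)
        if has_gamma:
            g = _gamma_burst(gamma_rng, fs, 0.2,
                             params.gamma_amplitude_sd * params.background_sd)
            add_waveform(focal_idx, t - 0.2, g)
        add_waveform(focal_idx, t + _SPIKE_LEAD_S, template)
        events.append(Event(t, IED_EVENT_DURATION_S, "IED", focal_names,
                            source="manual", has_gamma=has_gamma))

    # --- bursts ----------------------------------------------------------
    burst_rng = _rng(params.seed, "burst")
    n_burst = int(burst_rng.poisson(params.burst_rate * dur / 60.0))
    width = params.burst_duration
    onsets = _draw_onsets(burst_rng, n_burst, margin, dur - margin, occupied,
                          width + 0.5)
    for t in sorted(onsets):
        step = 0.25   # 4-Hz spike train within the burst
        k = _SPIKE_LEAD_S
        while k + 0.1 < width:
            add_waveform(focal_idx, t + k, template)
            k += step
        events.append(Event(t, width, "burst", focal_names, source="manual"))

    # --- spindles (N2 only) ----------------------------------------------
    spin_rng = _rng(params.seed, "spindle")
    spin_idx = np.array([CHANNELS_1020.index(c) for c in SPINDLE_CHANNELS])
    n2 = _n2_like_intervals(hypnogram)
    n2 = [(a, min(b, dur)) for a, b in n2 if a < dur]
    n2_minutes = sum(b - a for a, b in n2) / 60.0
    for rate, freq in ((params.spindle_rate_n2, params.spindle_freq),
                       (params.slow_spindle_rate_n2, params.slow_spindle_freq)):
        if rate <= 0 or n2_minutes <= 0:
            continue
        n_spin = int(spin_rng.poisson(rate * n2_minutes))
        lengths = np.array([b - a for a, b in n2], dtype=float)
        for _ in range(n_spin):
            sdur = float(spin_rng.uniform(0.8, 2.0))
            eligible = [iv for iv, ln in zip(n2, lengths) if ln > sdur + 1.0]
            if not eligible:
                continue
            iv = eligible[int(spin_rng.integers(len(eligible)))]
            for _attempt in range(200):
                t = float(spin_rng.uniform(iv[0] + 0.5, iv[1] - sdur - 0.5))
                span = (t - 0.5, t + sdur + 0.5)
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    break
            else:
                raise GenerationError("spindle placement retry budget exhausted")
            phase = float(spin_rng.uniform(0, 2 * np.pi))
            wave = spindle_template(fs, freq, sdur, amp_spin, phase)
            add_waveform(spin_idx, t, wave)
            events.append(Event(t, sdur, "spindle", SPINDLE_CHANNELS,
                                source="manual", freq_hz=freq))

    out = Recording(sig, fs, rec.channel_names, montage=rec.montage,
                    recording_id=rec.recording_id)
    gt = GroundTruth(EventSet(sorted(events, key=lambda e: e.onset),
                              rec.recording_id), hypnogram)
    return out, gt


def generate_recording(params: SynthParams
                       ) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Background + hypnogram + injected events in one call."""
    hyp = generate_hypnogram(params)
    rec = generate_background(params)
    rec, gt = inject_events(rec, params, hyp)
    return rec, hyp, gt


# ---------------------------------------------------------------------------
# annotations for detector training
# ---------------------------------------------------------------------------

def make_annotations(gt: GroundTruth, duration: float, n_ieds: int = 10,
                     background_s: float = 10.0) -> EventSet:
    """Emulate the visual marking protocol on ground truth.

    Takes the first ``n_ieds`` injected IEDs as manual IED annotations and
    carves event-free gaps into background segments totalling at least
    ``background_s`` seconds.
    """
    ieds = [e for e in gt.events if e.type == "IED"][:n_ieds]
    if len(ieds) < n_ieds:
        raise GenerationError(
            f"only {len(ieds)} IEDs available for annotation, need {n_ieds}")
    busy = union_intervals([(e.span()[0] - 0.5, e.span()[1] + 0.5)
                            for e in gt.events])
    gaps: list[tuple[float, float]] = []
    prev = 0.0
    for a, b in busy:
        if a > prev:
            gaps.append((prev, a))
        prev = max(prev, b)
    if prev < duration:
        gaps.append((prev, duration))
    gaps.sort(key=lambda iv: iv[1] - iv[0], reverse=True)
    segments: list[Event] = []
    acc = 0.0
    for a, b in gaps:
        if acc >= background_s:
            break
        take = min(b - a, background_s - acc + 2.0, 20.0)
        if take < 1.0:
            continue
        segments.append(Event(a, take, "background", (), source="manual"))
        acc += take
    if acc < background_s:
        raise GenerationError(
            f"could not find {background_s} s of event-free background")
    out = [Event(e.onset, e.duration, "IED", e.channels, source="manual")
           for e in ieds] + segments
    return EventSet(sorted(out, key=lambda e: e.onset), gt.events.recording_id)


# ---------------------------------------------------------------------------
# paired cohorts
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecording:
    """One arm of a subject: signal (optional), hypnogram, ground truth."""

    recording: Recording | None
    hypnogram: Hypnogram
    ground_truth: GroundTruth
    params: SynthParams


@dataclass
class SubjectPair:
    subject_id: str
    pre: SubjectRecording
    post: SubjectRecording


def baseline_params(**overrides) -> SynthParams:
    """Default pre-treatment calibration.

    An IED rate of 12.96/min yields a nominal burden of 5.4%
    (12.96 x 0.25 s / 60 s); fast spindles at 0.8/min of N2 and slow
    spindles at 0.3/min.
    """
    base = dict(ied_rate=12.96, spindle_rate_n2=0.8, spindle_freq=13.0,
                slow_spindle_rate_n2=0.3, slow_spindle_freq=11.0)
    base.update(overrides)
    return SynthParams(**base)


def followup_params(**overrides) -> SynthParams:
    """Default post-treatment calibration: burden 1.5%, fast spindles 1.5/min."""
    base = dict(ied_rate=3.6, spindle_rate_n2=1.5, spindle_freq=13.0,
                slow_spindle_rate_n2=0.3, slow_spindle_freq=11.0)
    base.update(overrides)
    return SynthParams(**base)


def generate_paired_cohort(n_subjects: int,
                           pre: SynthParams | None = None,
                           post: SynthParams | None = None,
                           seed: int = 0,
                           between_sigma: float = 1.0,
                           within_sigma: float = 0.5,
                           spindle_sigma: float = 0.5,
                           render: bool = True,
                           min_pre_events: int = 0) -> list[SubjectPair]:
    """Paired pre/post cohort with lognormal between-subject dispersion.

    Per-subject IED (and burst) rates are the nominal rates times a shared
    lognormal subject factor; the post arm gets an extra within-subject
    lognormal factor, so cohort medians track the nominal rates.  Rates are
    capped so nominal event occupancy stays below half the recording
    (placement with overlap rejection saturates well before full packing).

    ``min_pre_events > 0`` emulates the clinical inclusion criterion of a
    high baseline burden: subjects whose pre arm draws fewer IEDs are
    redrawn (deterministically).  Leave at 0 for null-calibration studies,
    where conditioning only the pre arm would bias paired differences.
    With ``render=False`` only hypnograms and ground-truth event sets are
    drawn (fast path for Monte-Carlo studies of the event-time budget).
    """
    if n_subjects < 2:
        raise ParameterError("n_subjects must be >= 2")
    pre = pre or baseline_params()
    post = post or followup_params()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(99,)))
    cohort: list[SubjectPair] = []
    for i in range(n_subjects):
        z = rng.standard_normal()
        w = rng.standard_normal()
        zs = rng.standard_normal()
        ws = rng.standard_normal()
        m_pre = math.exp(between_sigma * z)
        m_post = m_pre * math.exp(within_sigma * w)
        s_pre = math.exp(spindle_sigma * zs)
        s_post = s_pre * math.exp(spindle_sigma * 0.5 * ws)
        seed_pre = int(rng.integers(2 ** 31))
        seed_post = int(rng.integers(2 ** 31))
        # cap so the 0.5-s placement footprints occupy < 45% of the recording
        # (random sequential packing stalls well before full coverage); this
        # truncates the extreme high-burden tail at ~22% nominal burden
        max_rate = 0.45 * 60.0 / 0.5
        p_pre = replace(pre, ied_rate=min(pre.ied_rate * m_pre, max_rate),
                        burst_rate=pre.burst_rate * m_pre,
                        spindle_rate_n2=pre.spindle_rate_n2 * s_pre,
                        seed=seed_pre)
        p_post = replace(post, ied_rate=min(post.ied_rate * m_post, max_rate),
                         burst_rate=post.burst_rate * m_post,
                         spindle_rate_n2=post.spindle_rate_n2 * s_post,
                         seed=seed_post)

        def build(p: SynthParams) -> SubjectRecording:
            hyp = generate_hypnogram(p)
            if render:
                rec = generate_background(p)
                rec, gt = inject_events(rec, p, hyp)
                rec = replace(rec, recording_id=f"s{i:02d}-" + rec.recording_id)
            else:
                rec = None
                gt = _events_only(p, hyp)
            return SubjectRecording(rec, hyp, gt, p)

        arm_pre = build(p_pre)
        for _redraw in range(20):
            if min_pre_events <= 0 or \
                    len(arm_pre.ground_truth.events.of_type("IED")) \
                    >= min_pre_events:
                break
            p_pre = replace(p_pre, ied_rate=min(p_pre.ied_rate * 1.3, max_rate),
                            seed=int(rng.integers(2 ** 31)))
            arm_pre = build(p_pre)
        else:
            raise GenerationError(
                f"subject {i}: could not draw {min_pre_events} baseline IEDs")
        cohort.append(SubjectPair(f"s{i:02d}", arm_pre, build(p_post)))
    return cohort


def _events_only(params: SynthParams, hyp: Hypnogram) -> GroundTruth:
    """Ground-truth event draw without signal synthesis (same substreams)."""
    dur = params.duration
    occupied: list[tuple[float, float]] = []
    events: list[Event] = []
    focal_rng = _rng(params.seed, "focal")
    focal_idx = np.sort(focal_rng.choice(len(CHANNELS_1020),
                                         size=params.n_focal_channels,
                                         replace=False))
    focal_names = tuple(CHANNELS_1020[i] for i in focal_idx)
    margin = 0.6
    ied_rng = _rng(params.seed, "ied")
    n_ied = int(ied_rng.poisson(params.ied_rate * dur / 60.0))
    gamma_rng = _rng(params.seed, "gamma")
    for t in sorted(_draw_onsets(ied_rng, n_ied, margin, dur - margin,
                                 occupied, 0.5)):
        has_gamma = bool(gamma_rng.uniform() < params.gamma_precursor_fraction)
        events.append(Event(t, IED_EVENT_DURATION_S, "IED", focal_names,
                            source="manual", has_gamma=has_gamma))
    burst_rng = _rng(params.seed, "burst")
    n_burst = int(burst_rng.poisson(params.burst_rate * dur / 60.0))
    for t in sorted(_draw_onsets(burst_rng, n_burst, margin, dur - margin,
                                 occupied, params.burst_duration + 0.5)):
        events.append(Event(t, params.burst_duration, "burst", focal_names,
                            source="manual"))
    return GroundTruth(EventSet(sorted(events, key=lambda e: e.onset),
                                f"synth-{params.seed}"), hyp)
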