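"""Windowed IED detector: channel-label extraction, training, calibration.

The detector scores 500-ms single-channel waveforms.  Channel-level labels
are derived from global (non-lateralized) annotations by 2-medoid
clustering of the 19 per-channel waveforms under a Sakoe-Chiba-banded DTW
distance; the cluster whose medoid has the larger peak-to-peak amplitude is
taken as event-bearing.  Training runs under leave-one-patient-out folds
and a model refuses to score recordings from its own training fold.
Inference slides the window with 75% overlap (125-ms hop) and combines the
19 per-channel probabilities with a maximum.

The window classifier is pluggable.  The default is a logistic model on
spectral/morphology features, which trains in seconds on a CPU; any object
with ``fit(X, y)`` and ``predict_proba(X)`` over raw windows can be
substituted.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats as spstats

from .errors import (CalibrationError, LeakageError, ParameterError,
                     TrainingError, ValidationError)
from .io import Event, EventSet, Recording

try:                                    # optional JIT for the DTW kernel
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:                       # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    """Window geometry and calibration policy."""

    window_s: float = 0.5
    inference_overlap: float = 0.75
    min_calibration_sensitivity: float = 0.75
    min_annotated_ieds: int = 10
    min_background_s: float = 10.0
    threshold_step: float = 0.02
    #: visual re-thresholding surrogate fires only on gross rate deviations;
    #: annotated segments are event-enriched, so their IED rate
    #: overestimates the recording-wide rate by an order of magnitude
    rate_tolerance_factor: float = 20.0
    dtw_band_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inference_overlap < 1:
            raise ParameterError("inference_overlap must lie in (0, 1)")
        if not 0 < self.min_calibration_sensitivity <= 1:
            raise ParameterError("min_calibration_sensitivity must lie in (0, 1]")
        if self.window_s <= 0:
            raise ParameterError("window_s must be > 0")

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.inference_overlap)


def n_windows(duration: float, params: DetectionParams) -> int:
    """Number of sliding windows fitting a recording of ``duration`` s."""
    if duration < params.window_s:
        return 0
    return int(math.floor((duration - params.window_s) / params.hop_s + 1e-9)) + 1


# ---------------------------------------------------------------------------
# DTW + 2-medoids
# ---------------------------------------------------------------------------

@_njit(cache=False)
def _dtw_kernel(x: np.ndarray, y: np.ndarray, band: int) -> float:
    n, m = x.shape[0], y.shape[0]
    big = 1e300
    prev = np.full(m + 1, big)
    cur = np.full(m + 1, big)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = big
        lo = max(1, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            c = x[i - 1] - y[j - 1]
            c = c * c
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return math.sqrt(prev[m])


def dtw_distance(x: np.ndarray, y: np.ndarray,
                 band_fraction: float = 0.1) -> float:
    """Sakoe-Chiba-banded DTW distance between two 1-D series."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    band = max(1, int(round(band_fraction * max(x.size, y.size))))
    return float(_dtw_kernel(x, y, band))


def _dtw_matrix(series: np.ndarray, band_fraction: float) -> np.ndarray:
    k = series.shape[0]
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = dtw_distance(series[i], series[j],
                                             band_fraction)
    return d


def two_medoids(dist: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Exact 2-medoid partition by exhaustive medoid-pair search.

    Returns (labels in {0,1}, (medoid0, medoid1)).  Ties between equidistant
    points go to cluster 0.
    """
    k = dist.shape[0]
    best_cost = np.inf
    best = (0, min(1, k - 1))
    for a in range(k):
        for b in range(a + 1, k):
            cost = np.minimum(dist[a], dist[b]).sum()
            if cost < best_cost - 1e-12:
                best_cost = cost
                best = (a, b)
    a, b = best
    labels = (dist[b] < dist[a]).astype(int)
    labels[a], labels[b] = 0, 1
    return labels, best


# ---------------------------------------------------------------------------
# channel-level annotation extraction
# ---------------------------------------------------------------------------

@dataclass
class WindowDataset:
    """Labeled 500-ms windows (raw waveforms) from one recording."""

    X: np.ndarray            # (n_windows, window_samples)
    y: np.ndarray            # 1 = IED-positive channel window
    recording_id: str = "rec"

    def __add__(self, other: "WindowDataset") -> "WindowDataset":
        return WindowDataset(np.vstack([self.X, other.X]),
                             np.concatenate([self.y, other.y]),
                             self.recording_id)


def _event_window(rec: Recording, center: float, params: DetectionParams
                  ) -> np.ndarray | None:
    fs = rec.sampling_rate
    w = int(round(params.window_s * fs))
    a = int(round(center * fs)) - w // 2
    if a < 0 or a + w > rec.n_samples:
        return None
    return rec.signal[:, a:a + w]


def extract_channel_annotations(rec: Recording, annotated: EventSet,
                                params: DetectionParams | None = None,
                                max_negatives: int | None = None,
                                ) -> WindowDataset:
    """Turn global annotations into channel-level labeled windows.

    For every annotated IED the 19 per-channel windows centered on the
    event are split into two clusters under DTW distance; channels in the
    cluster whose medoid has the larger peak-to-peak amplitude become
    positive examples, the rest negative.  If the waveforms are essentially
    identical across channels (no separation possible) all channels are
    labeled positive.  Background segments contribute negative windows on
    all channels.
    """
    params = params or DetectionParams()
    if rec.n_channels < 2:
        raise ValidationError("channel-annotation extraction needs >= 2 channels")
    fs = rec.sampling_rate
    w = int(round(params.window_s * fs))
    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []

    for ev in annotated.of_type("IED"):
        center = ev.onset + (ev.duration / 2.0 if ev.duration > 0 else 0.0)
        windows = _event_window(rec, center, params)
        if windows is None:
            import warnings
            warnings.warn(f"event at {ev.onset:.2f}s too close to an edge; skipped")
            continue
        ds = windows[:, ::2] if fs >= 200 else windows   # decimate for DTW
        dist = _dtw_matrix(ds, params.dtw_band_fraction)
        if dist.max() < 1e-6 * max(1.0, float(np.abs(ds).max())):
            pos.extend(windows)     # degenerate: identical everywhere
            continue
        labels, (a, b) = two_medoids(dist)
        ptp = np.ptp(windows, axis=1)
        positive_cluster = 0 if ptp[a] >= ptp[b] else 1
        for ch in range(rec.n_channels):
            (pos if labels[ch] == positive_cluster else neg).append(windows[ch])

    for ev in annotated.of_type("background"):
        a = int(round(ev.onset * fs))
        b = int(round(ev.offset * fs))
        for start in range(a, b - w + 1, w):
            neg.extend(rec.signal[:, start:start + w])

    if max_negatives is not None and len(neg) > max_negatives:
        sel = np.random.default_rng(params.seed).choice(
            len(neg), size=max_negatives, replace=False)
        neg = [neg[i] for i in sorted(sel)]

    X = np.array(pos + neg) if (pos or neg) else np.empty((0, w))
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return WindowDataset(X, y, rec.recording_id)


# ---------------------------------------------------------------------------
# window classifier
# ---------------------------------------------------------------------------

_BANDS = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 70.0))


def window_features(X: np.ndarray, fs: float) -> np.ndarray:
    """Spectral + morphology features for a batch of raw windows."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[1]
    eps = 1e-12
    spec = np.abs(np.fft.rfft(X, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    feats = []
    for lo, hi in _BANDS:
        m = (freqs >= lo) & (freqs < min(hi, fs / 2))
        feats.append(np.log(spec[:, m].sum(axis=1) + eps))
    d1 = np.diff(X, axis=1)
    d2 = np.diff(X, n=2, axis=1)
    feats.append(np.log(np.ptp(X, axis=1) + eps))
    feats.append(np.log(X.std(axis=1) + eps))
    feats.append(np.log(np.abs(d1).sum(axis=1) + eps))       # line length
    feats.append(np.log(np.abs(d2).max(axis=1) + eps))       # sharpness
    # constant windows have undefined kurtosis; map them to 0
    feats.append(np.nan_to_num(spstats.kurtosis(X, axis=1)))
    return np.column_stack(feats)


class FeatureWindowClassifier:
    """Logistic regression on window features; the dependency-light default.

    Implements the window-classifier protocol: ``fit(X, y)`` /
    ``predict_proba(X)`` on raw (n_windows, window_samples) arrays.
    """

    def __init__(self, fs: float, seed: int = 0, C: float = 1.0):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        self.fs = fs
        self._pipe = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=C, max_iter=2000, random_state=seed))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeatureWindowClassifier":
        self._pipe.fit(window_features(X, self.fs), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the IED class for each raw window."""
        if X.shape[0] == 0:
            return np.empty(0)
        p = self._pipe.predict_proba(window_features(X, self.fs))
        return p[:, list(self._pipe.classes_).index(1)]


# ---------------------------------------------------------------------------
# model + training
# ---------------------------------------------------------------------------

@dataclass
class DetectorModel:
    """Per-fold window classifiers with a training manifest.

    ``classifiers[p]`` was trained on every patient except ``p`` (LOPO);
    scoring any training-fold recording through the wrong fold raises
    :class:`LeakageError`.
    """

    classifiers: dict[str, object]
    training_patients: tuple[str, ...]
    params: DetectionParams
    thresholds: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def classifier_for(self, patient_id: str):
        if patient_id in self.classifiers:
            return self.classifiers[patient_id]
        if patient_id in self.training_patients:
            raise LeakageError(
                f"no leakage-free fold available for patient {patient_id!r}")
        # unseen patient: any fold is leakage-free; use the first deterministically
        return self.classifiers[min(self.classifiers)]

    def score_windows(self, fold_id: str, patient_id: str,
                      X: np.ndarray) -> np.ndarray:
        """Score raw windows with a named fold, enforcing the LOPO contract."""
        if patient_id != fold_id and patient_id in self.training_patients:
            raise LeakageError(
                f"fold {fold_id!r} was trained on patient {patient_id!r}")
        return self.classifiers[fold_id].predict_proba(X)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "DetectorModel":
        with Path(path).open("rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, DetectorModel):
            raise ValidationError(f"{path} is not a detector model archive")
        return model


def _check_minimums(patient: str, annotated: EventSet,
                    params: DetectionParams) -> None:
    n_ied = len(annotated.of_type("IED"))
    bg = sum(e.duration for e in annotated.of_type("background"))
    if n_ied < params.min_annotated_ieds:
        raise TrainingError(
            f"recording {patient!r}: {n_ied} annotated IEDs "
            f"< required {params.min_annotated_ieds}")
    if bg < params.min_background_s:
        raise TrainingError(
            f"recording {patient!r}: {bg:.1f} s annotated background "
            f"< required {params.min_background_s} s")


def train_detector(cohort: Mapping[str, tuple[Recording, EventSet]],
                   params: DetectionParams | None = None,
                   classifier_factory=None,
                   max_negatives_per_recording: int = 1500,
                   ) -> DetectorModel:
    """Train LOPO window classifiers from annotated recordings.

    ``cohort`` maps patient id -> (recording, annotated EventSet carrying
    >= ``min_annotated_ieds`` IEDs and >= ``min_background_s`` s of
    background).  Deterministic under a fixed ``params.seed``.
    """
    params = params or DetectionParams()
    if len(cohort) < 2:
        raise TrainingError("LOPO training needs at least 2 patients")
    fs_set = {rec.sampling_rate for rec, _ in cohort.values()}
    if len(fs_set) != 1:
        raise TrainingError("all training recordings must share a sampling rate")
    fs = fs_set.pop()
    if classifier_factory is None:
        def classifier_factory():
            return FeatureWindowClassifier(fs, seed=params.seed)

    datasets: dict[str, WindowDataset] = {}
    for patient in sorted(cohort):
        rec, annotated = cohort[patient]
        _check_minimums(patient, annotated, params)
        datasets[patient] = extract_channel_annotations(
            rec, annotated, params, max_negatives=max_negatives_per_recording)

    classifiers: dict[str, object] = {}
    for held_out in sorted(datasets):
        train_ids = [p for p in sorted(datasets) if p != held_out]
        X = np.vstack([datasets[p].X for p in train_ids])
        y = np.concatenate([datasets[p].y for p in train_ids])
        clf = classifier_factory()
        clf.fit(X, y)
        classifiers[held_out] = clf

    manifest = {
        "patients": sorted(datasets),
        "window_counts": {p: int(len(d.y)) for p, d in datasets.items()},
        "positive_counts": {p: int(d.y.sum()) for p, d in datasets.items()},
        "seed": params.seed,
        "sampling_rate": fs,
    }
    return DetectorModel(classifiers, tuple(sorted(datasets)), params,
                         manifest=manifest)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class WindowScores:
    """Sliding-window scores for one recording."""

    starts: np.ndarray           # window start times, s
    global_scores: np.ndarray    # max over channels, per window
    channel_scores: np.ndarray   # (n_channels, n_windows)
    channel_names: tuple[str, ...]
    params: DetectionParams
    duration: float
    recording_id: str = "rec"


def predict_global(model: DetectorModel, rec: Recording, patient_id: str,
                   params: DetectionParams | None = None) -> WindowScores:
    """Score a recording window-by-window; global score = channel maximum."""
    params = params or model.params
    fs = rec.sampling_rate
    if model.manifest and abs(fs - model.manifest.get("sampling_rate", fs)) > 1e-9:
        raise ValidationError("sampling rate differs from the training cohort")
    w = int(round(params.window_s * fs))
    hop = params.hop_s
    nw = n_windows(rec.duration, params)
    if nw == 0:
        raise ValidationError("recording shorter than one analysis window")
    starts = np.arange(nw) * hop
    idx = np.round(starts * fs).astype(int)
    fold = patient_id if patient_id in model.classifiers else None
    # stack all channel windows into one batch for a single classifier call
    wins = np.stack([rec.signal[:, i:i + w] for i in idx], axis=1)
    flat = wins.reshape(rec.n_channels * nw, w)
    if fold is not None:
        probs = model.score_windows(fold, patient_id, flat)
    else:
        probs = model.classifier_for(patient_id).predict_proba(flat)
    channel_scores = probs.reshape(rec.n_channels, nw)
    return WindowScores(starts, channel_scores.max(axis=0), channel_scores,
                        rec.channel_names, params, rec.duration,
                        rec.recording_id)


# ---------------------------------------------------------------------------
# event extraction and calibration
# ---------------------------------------------------------------------------

def _peak_windows(scores: np.ndarray, min_separation: int = 1) -> np.ndarray:
    """Indices of local maxima (plateaus collapsed to their first window).

    Maxima closer than ``min_separation`` windows are merged keeping the
    larger one.  The peak set does not depend on any threshold, so
    thresholded event counts are monotone non-increasing in the threshold.
    """
    n = scores.size
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[j + 1] == scores[i]:
            j += 1
        left = scores[i - 1] if i > 0 else -np.inf
        right = scores[j + 1] if j + 1 < n else -np.inf
        if scores[i] > left and scores[i] > right:
            peaks.append(i)
        i = j + 1
    if not peaks:
        peaks = [int(np.argmax(scores))]
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] <= min_separation:
            if scores[p] > scores[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return np.array(merged, dtype=int)


def detect_ieds(scores: WindowScores, threshold: float,
                params: DetectionParams | None = None) -> EventSet:
    """Threshold window scores into an IED EventSet.

    Each detected event sits at a supra-threshold local maximum of the
    global score series; score maxima within one window length of each
    other count once, so the overlapping windows sliding across a single
    discharge collapse into one event while supra-threshold runs separated
    by a hop or more stay distinct.  The event time is the midpoint of the
    contiguous supra-threshold run around the peak (clipped to one window
    length on each side); channels whose own probability reaches the
    threshold at the peak window are attributed to the event.
    """
    params = params or scores.params
    per_window = max(int(round(params.window_s / params.hop_s)), 1)
    peaks = _peak_windows(scores.global_scores, min_separation=per_window)
    g = scores.global_scores
    events: list[Event] = []
    for p in peaks:
        s = float(g[p])
        if s < threshold:
            continue
        lo = p
        while lo > 0 and g[lo - 1] >= threshold and p - lo < per_window:
            lo -= 1
        hi = p
        while hi + 1 < g.size and g[hi + 1] >= threshold and hi - p < per_window:
            hi += 1
        center = (scores.starts[lo] + scores.starts[hi] + params.window_s) / 2.0
        chans = tuple(name for k, name in enumerate(scores.channel_names)
                      if scores.channel_scores[k, p] >= threshold)
        onset = max(center - 0.125, 0.0)
        events.append(Event(onset, 0.25, "IED", chans, source="detected",
                            score=s))
    return EventSet(events, scores.recording_id)


def _event_peak_scores(scores: WindowScores, annotated: EventSet) -> np.ndarray:
    """Best global window score overlapping each annotated IED span."""
    w = scores.params.window_s
    out = []
    for ev in annotated.of_type("IED"):
        a, b = ev.span()
        m = (scores.starts < b) & (scores.starts + w > a)
        out.append(scores.global_scores[m].max() if m.any() else 0.0)
    return np.asarray(out)


def sensitivity_at(scores: WindowScores, annotated: EventSet,
                   threshold: float) -> float:
    """Fraction of annotated IEDs whose best window score >= threshold."""
    ev = _event_peak_scores(scores, annotated)
    if ev.size == 0:
        raise CalibrationError("no annotated IEDs to compute sensitivity")
    return float(np.mean(ev >= threshold))


def calibrate_threshold(scores: WindowScores, annotated: EventSet,
                        params: DetectionParams | None = None) -> float:
    """Largest threshold meeting the sensitivity floor, then rate-adjusted.

    Thresholds live on the ``threshold_step`` grid: the calibrated value is
    the largest grid point not exceeding the k-th largest annotated-event
    score, where k is the smallest count satisfying the sensitivity floor
    (so the floor holds by construction).  A deterministic surrogate of
    visual re-thresholding follows: while the full-recording detection rate
    deviates from the annotated-segment IED rate by more than
    ``rate_tolerance_factor``, move the threshold in ``threshold_step``
    increments -- never crossing the sensitivity floor.
    """
    params = params or scores.params
    n_ied = len(annotated.of_type("IED"))
    bg_s = sum(e.duration for e in annotated.of_type("background"))
    if n_ied < params.min_annotated_ieds:
        raise CalibrationError(
            f"{n_ied} annotated IEDs < required {params.min_annotated_ieds}")
    if bg_s < params.min_background_s:
        raise CalibrationError(
            f"{bg_s:.1f} s annotated background < required "
            f"{params.min_background_s} s")

    ev_scores = np.sort(_event_peak_scores(scores, annotated))[::-1]
    k = int(math.ceil(params.min_calibration_sensitivity * n_ied - 1e-9))
    kth = float(ev_scores[k - 1])
    step = params.threshold_step
    threshold = max(math.floor(kth / step + 1e-9) * step, step)
    if threshold > kth:   # k-th score below one step: fall back to it exactly
        threshold = kth

    # deterministic surrogate of the visual adjustment step
    annotated_span_s = n_ied * 0.25 + bg_s
    ref_rate = n_ied / (annotated_span_s / 60.0)
    factor = params.rate_tolerance_factor
    for _ in range(200):
        det = detect_ieds(scores, threshold, params)
        det_rate = len(det) / (scores.duration / 60.0)
        if det_rate > factor * ref_rate:
            cand = threshold + params.threshold_step
            if cand > 1.0 or sensitivity_at(scores, annotated, cand) \
                    < params.min_calibration_sensitivity:
                break
            threshold = cand
        elif det_rate < ref_rate / factor and threshold > params.threshold_step:
            threshold -= params.threshold_step
        else:
            break
    if sensitivity_at(scores, annotated, threshold) \
            < params.min_calibration_sensitivity:
        raise CalibrationError("no threshold attains the sensitivity floor")
    return threshold
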