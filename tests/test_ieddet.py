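import itertools

import numpy as np
import pytest

from conftest import match_fraction
from qeeg import ieddet, io, synthio
from qeeg.errors import (CalibrationError, LeakageError, ParameterError,
                         TrainingError)
from qeeg.ieddet import DetectionParams, WindowScores


# ---------------------------------------------------------------------------
# DTW + medoids
# ---------------------------------------------------------------------------

def dtw_oracle(x, y):
    """Full (unbanded) DTW by plain dynamic programming."""
    n, m = len(x), len(y)
    d = np.full((n + 1, m + 1), np.inf)
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = (x[i - 1] - y[j - 1]) ** 2
            d[i, j] = c + min(d[i - 1, j], d[i, j - 1], d[i - 1, j - 1])
    return float(np.sqrt(d[n, m]))


class TestDtw:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).standard_normal(40)
        assert ieddet.dtw_distance(x, x) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        assert ieddet.dtw_distance(x, y) == pytest.approx(
            ieddet.dtw_distance(y, x))

    def test_matches_full_dp_oracle_with_wide_band(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.standard_normal(20), rng.standard_normal(20)
            assert ieddet.dtw_distance(x, y, band_fraction=1.0) \
                == pytest.approx(dtw_oracle(x, y))

    def test_shift_invariance_within_band(self):
        # a warped copy should be much closer than an unrelated series
        t = np.linspace(0, 1, 60)
        a = np.sin(2 * np.pi * 3 * t)
        b = np.sin(2 * np.pi * 3 * (t - 0.03))
        c = np.sin(2 * np.pi * 7 * t + 1.0)
        assert ieddet.dtw_distance(a, b) < ieddet.dtw_distance(a, c)


def medoid_oracle(dist):
    """Brute-force 2-medoid search over every medoid pair."""
    k = dist.shape[0]
    best, best_cost = None, np.inf
    for a, b in itertools.combinations(range(k), 2):
        cost = np.minimum(dist[a], dist[b]).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, (a, b)
    return best, best_cost


class TestTwoMedoids:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pts = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 9)])
        dist = np.abs(pts[:, None] - pts[None, :])
        labels, medoids = ieddet.two_medoids(dist)
        (oa, ob), oracle_cost = medoid_oracle(dist)
        cost = np.minimum(dist[medoids[0]], dist[medoids[1]]).sum()
        assert cost == pytest.approx(oracle_cost)
        assert len(set(labels[pts < 5])) == 1
        assert len(set(labels[pts > 5])) == 1
        assert labels[0] != labels[-1]


class TestChannelAnnotationExtraction:
    def _rec_with_event(self, event_channels, amplitude=120.0, noise=5.0):
        fs = 256.0
        rng = np.random.default_rng(4)
        sig = rng.normal(0, noise, (19, int(10 * fs)))
        template = synthio.ied_template(fs, amplitude)
        for ch in event_channels:
            i = io.CHANNELS_1020.index(ch)
            sig[i, 1280:1280 + template.size] += template
        rec = io.Recording(sig, fs, io.CHANNELS_1020)
        onset = 1280 / fs - 0.09   # event span centered on the spike
        events = io.EventSet([io.Event(onset, 0.25, "IED", (), "manual")])
        return rec, events

    def test_event_channels_labeled_positive(self):
        wanted = ("F3", "C3", "P3")
        rec, events = self._rec_with_event(wanted)
        ds = ieddet.extract_channel_annotations(rec, events)
        assert int(ds.y.sum()) == 3
        # the positive windows are exactly the event-bearing channels
        pos = ds.X[ds.y == 1]
        assert {float(np.ptp(w)) > 100 for w in pos} == {True}

    def test_identical_waveform_everywhere_all_positive(self):
        fs = 256.0
        t = np.arange(int(5 * fs)) / fs
        wave = 50 * np.sin(2 * np.pi * 4 * t)
        rec = io.Recording(np.tile(wave, (19, 1)), fs, io.CHANNELS_1020)
        events = io.EventSet([io.Event(2.0, 0.25, "IED", (), "manual")])
        ds = ieddet.extract_channel_annotations(rec, events)
        assert int(ds.y.sum()) == 19

    def test_edge_event_skipped_with_warning(self):
        rec, _ = self._rec_with_event(("Cz",))
        events = io.EventSet([io.Event(0.01, 0.25, "IED", (), "manual")])
        with pytest.warns(UserWarning):
            ds = ieddet.extract_channel_annotations(rec, events)
        assert len(ds.y) == 0


# ---------------------------------------------------------------------------
# window arithmetic and score combination
# ---------------------------------------------------------------------------

class TestWindows:
    def test_count_for_ten_seconds(self):
        params = DetectionParams()
        assert params.hop_s == pytest.approx(0.125)
        assert ieddet.n_windows(10.0, params) == 77

    def test_shorter_than_window(self):
        assert ieddet.n_windows(0.3, DetectionParams()) == 0

    @pytest.mark.parametrize("bad", [dict(inference_overlap=1.0),
                                     dict(min_calibration_sensitivity=0.0),
                                     dict(window_s=-1.0)])
    def test_invalid_params(self, bad):
        with pytest.raises(ParameterError):
            DetectionParams(**bad)


class _StubClassifier:
    """Scores windows by which channel block they came from."""

    def __init__(self, per_channel, n_windows):
        self.per_channel = per_channel
        self.n = n_windows

    def predict_proba(self, X):
        reps = X.shape[0] // len(self.per_channel)
        return np.repeat(self.per_channel, reps)

    def fit(self, X, y):
        return self


def test_global_score_is_channel_maximum():
    fs = 64.0
    rec = io.Recording(np.zeros((19, int(10 * fs))), fs, io.CHANNELS_1020)
    per_channel = np.full(19, 0.1)
    per_channel[7] = 0.9
    params = DetectionParams()
    model = ieddet.DetectorModel(
        {"pX": _StubClassifier(per_channel, ieddet.n_windows(10.0, params))},
        ("pX",), params)
    scores = ieddet.predict_global(model, rec, "pX", params)
    assert np.allclose(scores.global_scores, 0.9)
    assert np.allclose(scores.channel_scores[7], 0.9)
    assert np.allclose(scores.channel_scores[0], 0.1)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _scores_with_events(event_scores, background=0.05, hop=0.125,
                        duration=120.0):
    """WindowScores with chosen peak scores at separated event locations."""
    params = DetectionParams()
    nw = ieddet.n_windows(duration, params)
    g = np.full(nw, background)
    starts = np.arange(nw) * hop
    onsets = []
    for k, s in enumerate(event_scores):
        w = 40 + 16 * k               # every 2 s
        g[w] = s
        onsets.append(starts[w] + 0.25 - 0.125)
    scores = WindowScores(starts, g, np.tile(g, (19, 1)), io.CHANNELS_1020,
                          params, duration)
    events = [io.Event(max(o, 0.0), 0.25, "IED", (), "manual")
              for o in onsets]
    events.append(io.Event(duration - 15.0, 12.0, "background", (), "manual"))
    return scores, io.EventSet(events)


class TestCalibration:
    def test_order_statistic_example(self):
        scores, ann = _scores_with_events([0.9] * 8 + [0.6] * 2)
        thr = ieddet.calibrate_threshold(scores, ann)
        assert thr <= 0.9
        assert ieddet.sensitivity_at(scores, ann, thr) >= 0.8

    def test_floor_one_requires_min_score(self):
        scores, ann = _scores_with_events([0.9] * 8 + [0.6] * 2)
        params = DetectionParams(min_calibration_sensitivity=1.0)
        thr = ieddet.calibrate_threshold(scores, ann, params)
        assert thr <= 0.6
        assert ieddet.sensitivity_at(scores, ann, thr) == 1.0

    def test_sensitivity_floor_holds_over_random_scores(self):
        # oracle: exhaustive sweep over the threshold grid confirms both the
        # floor and that no larger grid threshold satisfies it
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ev = rng.uniform(0.2, 1.0, size=12)
            scores, ann = _scores_with_events(ev)
            params = DetectionParams()
            thr = ieddet.calibrate_threshold(scores, ann, params)
            sens = ieddet.sensitivity_at(scores, ann, thr)
            assert sens >= 0.75
            grid = np.arange(1, 51) * params.threshold_step
            admissible = [t for t in grid
                          if ieddet.sensitivity_at(scores, ann, t) >= 0.75]
            assert thr >= max(admissible) - 1e-9

    def test_too_few_annotations_raise(self):
        scores, ann = _scores_with_events([0.9] * 5)
        with pytest.raises(CalibrationError):
            ieddet.calibrate_threshold(scores, ann)


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

def _plain_scores(g, hop=0.125):
    params = DetectionParams()
    starts = np.arange(len(g)) * hop
    duration = starts[-1] + params.window_s
    return WindowScores(starts, np.asarray(g, dtype=float),
                        np.tile(g, (19, 1)).astype(float), io.CHANNELS_1020,
                        params, duration)


class TestDetectEvents:
    def test_four_consecutive_supra_windows_merge(self):
        g = [0.1] * 20 + [0.8, 0.9, 1.0, 0.9] + [0.1] * 20
        det = ieddet.detect_ieds(_plain_scores(g), 0.5)
        assert len(det) == 1

    def test_runs_two_seconds_apart_stay_distinct(self):
        g = [0.1] * 10 + [0.9, 0.95] + [0.1] * 16 + [0.85, 0.9] + [0.1] * 10
        det = ieddet.detect_ieds(_plain_scores(g), 0.5)
        assert len(det) == 2

    def test_channels_attributed_at_peak(self):
        g = np.array([0.1] * 10 + [0.9] + [0.1] * 10)
        scores = _plain_scores(g)
        scores.channel_scores = np.tile(g, (19, 1)) * 0.2
        scores.channel_scores[3] = g           # only F3 reaches threshold
        det = ieddet.detect_ieds(scores, 0.5)
        assert len(det) == 1
        assert det.events[0].channels == ("F3",)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(17)
        g = rng.beta(0.5, 3.0, size=400)
        scores = _plain_scores(g)
        counts = [len(ieddet.detect_ieds(scores, t))
                  for t in np.linspace(0.01, 0.99, 50)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# training / LOPO contract (uses the session-scoped trained cohort)
# ---------------------------------------------------------------------------

class TestTraining:
    def test_lopo_leakage_raises(self, trained_cohort):
        cohort, _, model = trained_cohort
        X = np.zeros((1, 128))
        with pytest.raises(LeakageError):
            model.score_windows("p00", "p01", X)

    def test_fold_scores_own_patient(self, trained_cohort):
        _, _, model = trained_cohort
        p = model.score_windows("p00", "p00", np.zeros((3, 128)))
        assert p.shape == (3,)
        assert np.all((0 <= p) & (p <= 1))

    def test_unseen_patient_gets_a_model(self, trained_cohort):
        _, _, model = trained_cohort
        clf = model.classifier_for("somebody-new")
        assert clf is not None

    def test_insufficient_annotations_name_recording(self):
        p = synthio.SynthParams(duration=60.0, ied_rate=10.0, seed=51)
        rec, _, gt = synthio.generate_recording(p)
        few = io.EventSet([e for e in gt.events.of_type("IED")][:3]
                          + [io.Event(0.0, 12.0, "background", (), "manual")],
                          "weak")
        with pytest.raises(TrainingError, match="weak"):
            ieddet.train_detector({"weak": (rec, few),
                                   "weak2": (rec, few)})

    def test_training_is_deterministic(self):
        from conftest import build_cohort
        cohort, _ = build_cohort(2, duration=60.0, seed0=300)
        m1 = ieddet.train_detector(cohort)
        m2 = ieddet.train_detector(cohort)
        rec, _ = cohort["p00"]
        s1 = ieddet.predict_global(m1, rec, "p00")
        s2 = ieddet.predict_global(m2, rec, "p00")
        assert np.array_equal(s1.global_scores, s2.global_scores)

    def test_flat_signal_scores_are_near_constant(self, trained_cohort):
        _, _, model = trained_cohort
        fs = model.manifest["sampling_rate"]
        rec = io.Recording(np.zeros((19, int(20 * fs))), fs,
                           io.CHANNELS_1020)
        scores = ieddet.predict_global(model, rec, "p00")
        assert scores.global_scores.std() < 1e-6

    def test_model_archive_round_trip(self, trained_cohort, tmp_path):
        cohort, _, model = trained_cohort
        path = tmp_path / "model.pkl"
        model.save(path)
        back = ieddet.DetectorModel.load(path)
        rec, _ = cohort["p00"]
        a = ieddet.predict_global(model, rec, "p00")
        b = ieddet.predict_global(back, rec, "p00")
        assert np.array_equal(a.global_scores, b.global_scores)


class TestEndToEnd:
    def test_detections_match_ground_truth(self, trained_cohort):
        cohort, truths, model = trained_cohort
        fractions = []
        for sid, (rec, ann) in cohort.items():
            scores = ieddet.predict_global(model, rec, sid)
            thr = ieddet.calibrate_threshold(scores, ann)
            assert ieddet.sensitivity_at(scores, ann, thr) >= 0.75
            det = ieddet.detect_ieds(scores, thr)
            fractions.append(match_fraction(det, truths[sid].events))
        assert min(fractions) >= 0.75

    def test_false_positive_rate_on_event_free_recording(self, trained_cohort):
        cohort, _, model = trained_cohort
        p = synthio.SynthParams(duration=120.0, ied_rate=0.0,
                                spindle_rate_n2=0.0, seed=999)
        rec = synthio.generate_background(p)
        scores = ieddet.predict_global(model, rec, "p00")
        det = ieddet.detect_ieds(scores, 0.5)
        # config target: below 1 false detection per minute on clean EEG
        assert len(det) / (rec.duration / 60.0) <= 1.0
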