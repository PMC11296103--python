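"""Shared fixtures: small trained cohorts, reused across detector tests."""

import numpy as np
import pytest

from qeeg import ieddet, synthio


def build_cohort(n, duration=120.0, seed0=100, **overrides):
    """Synthetic annotated cohort plus ground truths, keyed by patient id."""
    cohort, truths = {}, {}
    for i in range(n):
        params = synthio.SynthParams(duration=duration, ied_rate=10.0,
                                     spindle_rate_n2=1.0, seed=seed0 + i,
                                     **overrides)
        rec, hyp, gt = synthio.generate_recording(params)
        ann = synthio.make_annotations(gt, rec.duration)
        cohort[f"p{i:02d}"] = (rec, ann)
        truths[f"p{i:02d}"] = gt
    return cohort, truths


@pytest.fixture(scope="session")
def trained_cohort():
    """Six annotated recordings with a LOPO-trained detector."""
    cohort, truths = build_cohort(6)
    model = ieddet.train_detector(cohort)
    return cohort, truths, model


def match_fraction(detected, truth_events, tol=0.25):
    """Fraction of ground-truth IEDs with a detection within ``tol`` s."""
    truth = [e for e in truth_events if e.type == "IED"]
    hit = sum(1 for t in truth
              if any(abs(d.onset - t.onset) <= tol for d in detected))
    return hit / len(truth) if truth else float("nan")
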