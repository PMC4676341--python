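import numpy as np
import pytest

from npdkit import StabilityRule, TracingPoint, Phase
from npdkit.datasets import cf_reference_cohort
from npdkit.errors import StabilityError


@pytest.fixture(scope="session")
def cf_cohort():
    """Published reference values for the 11-patient CF group."""
    return cf_reference_cohort()


def brute_force_plateau(points, rule=StabilityRule()):
    """Exhaustive all-windows oracle for the plateau detector.

    Enumerates every (start, end) index pair spanning at least the stability
    window, keeps those whose PD range is strictly below the rule's maximum,
    and applies the same tie-break as the implementation: latest end time,
    then latest start.  Returns the window mean.
    """
    times = np.array([p.time for p in points])
    pds = np.array([p.pd for p in points])
    best = None  # (end_time, start_time, mean)
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            if times[j] - times[i] < rule.window:
                continue
            seg = pds[i : j + 1]
            if seg.max() - seg.min() >= rule.max_range:
                continue
            key = (times[j], times[i])
            if best is None or key > best[0]:
                best = (key, float(seg.mean()))
    if best is None:
        raise StabilityError("no stable window (oracle)")
    return best[1]


def make_phase_points(times, pds, phase=Phase.RINGER):
    return [TracingPoint(float(t), float(v), phase) for t, v in zip(times, pds)]


@pytest.fixture
def flat_phase():
    t = np.arange(0, 121, 1.0)
    return make_phase_points(t, np.full_like(t, -20.0))
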