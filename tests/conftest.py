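import numpy as np
import pytest

from scpopen.simulate import OPEN, SHUT, Dwell, IdealizedRecord

#: Table-2-like target open probabilities for the four cycle corners
TARGETS = {"glycine": 0.96, "beta-alanine": 0.54, "AMS": 0.85, "taurine": 0.12}


@pytest.fixture(scope="session")
def well_resolved_record():
    """Alternating open/shut dwells, every event at least 1 ms long.

    Durations are 1 ms plus an exponential tail so that threshold
    idealization of the rendered trace can be scored event by event.
    """
    rng = np.random.default_rng(7)
    durs = 1.0 + rng.exponential(4.0, size=400)
    dwells = [
        Dwell(OPEN if i % 2 == 0 else SHUT, float(d), 5.0 if i % 2 == 0 else 0.0)
        for i, d in enumerate(durs)
    ]
    return IdealizedRecord(dwells=dwells)


def match_open_events(truth_record, idealized, fs_out, min_true_ms=0.0):
    """Score recovered open events against ground truth.

    Each true open dwell is matched to the detected open dwell that covers
    its midpoint; returns (n_true, n_recovered, duration_errors_in_samples).
    """
    t = 0.0
    true_events = []
    for d in truth_record.dwells:
        if d.conducting and d.duration_ms >= min_true_ms:
            true_events.append((t, t + d.duration_ms))
        t += d.duration_ms
    t = 0.0
    det = []
    for d in idealized.dwells:
        if d.conducting:
            det.append((t, t + d.duration_ms))
        t += d.duration_ms
    starts = np.array([s for s, _ in det]) if det else np.empty(0)
    ends = np.array([e for _, e in det]) if det else np.empty(0)
    errors = []
    n_recovered = 0
    for s, e in true_events:
        mid = 0.5 * (s + e)
        hit = np.flatnonzero((starts <= mid) & (ends > mid))
        if hit.size == 1:
            n_recovered += 1
            errors.append(abs((ends[hit[0]] - starts[hit[0]]) - (e - s)) * fs_out / 1000.0)
    return len(true_events), n_recovered, np.asarray(errors)
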