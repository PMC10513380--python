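import numpy as np
import pytest

from nucleostruct.sim import EmSimParams, FrapSimParams, simulate_em_image


@pytest.fixture(scope="session")
def default_em_field():
    """One rendered EM field with ground truth, shared across detection tests."""
    return simulate_em_image(EmSimParams(seed=0))


@pytest.fixture()
def noiseless_half_params():
    return FrapSimParams(
        geometry="half", tau1=3.33, tau2=25.0, amp1=0.5, amp2=0.4, plateau=0.9,
        noise_sd=0.0, seed=1,
    )


def match_particles(truth, detected, size_class, match_radius_px):
    """Greedy one-to-one matching; returns (precision, recall)."""
    t = truth[truth["size_class"] == size_class]
    d = detected[detected["size_class"] == size_class]
    used = set()
    tp = 0
    for _, row in d.iterrows():
        dist = np.hypot(t["x_px"] - row["x_px"], t["y_px"] - row["y_px"])
        cands = [(dd, i) for dd, i in zip(dist, t.index) if dd < match_radius_px and i not in used]
        if cands:
            used.add(min(cands)[1])
            tp += 1
    precision = tp / len(d) if len(d) else 1.0
    recall = tp / len(t) if len(t) else 1.0
    return precision, recall
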