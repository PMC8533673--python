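import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_gini(labels, left_mask):
    """Independent Gini-decrease oracle from raw counts (pure Python)."""
    labels = [int(v) for v in labels]
    left = [l for l, m in zip(labels, left_mask) if m]
    right = [l for l, m in zip(labels, left_mask) if not m]
    if not left or not right:
        return None

    def gini(ys):
        n = len(ys)
        p1 = sum(ys) / n
        return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)

    n = len(labels)
    return gini(labels) - len(left) / n * gini(left) - len(right) / n * gini(right)


def brute_force_best_split(X, y):
    """Exhaustive all-features all-thresholds search; returns the best
    criterion value (None when no valid split exists)."""
    best = None
    n, p = X.shape
    for j in range(p):
        vals = sorted(set(X[:, j]))
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            dec = brute_force_gini(y, X[:, j] <= thr)
            if dec is not None and (best is None or dec > best):
                best = dec
    return best
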