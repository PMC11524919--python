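import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from olst import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> syn.CohortConfig:
    """A 20-child cohort with short trials: cheap but structurally
    identical to the full protocol."""
    from dataclasses import replace
    return replace(
        syn.default_config(),
        n_boys=10, n_girls=10,
        high_frac_by_sex={"male": 0.4, "female": 0.4},
        trial_cap=4.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return syn.generate_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    from olst import features as ft
    return ft.build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def one_trial():
    """A single mid-severity trial with its simulation diagnostics."""
    cfg = syn.default_config()
    rng = np.random.default_rng(42)
    return syn.simulate_trial(0.5, "right", cfg, rng, return_info=True)


# ----------------------------------------------------------- oracles

def apen_bruteforce(x, m, r):
    """Literal Pincus ApEn: template counting over all pairs."""
    x = np.asarray(x, dtype=float)
    N = len(x)

    def phi(mm):
        total = 0.0
        k = N - mm + 1
        for i in range(k):
            cnt = 0
            for j in range(k):
                if max(abs(x[i + t] - x[j + t]) for t in range(mm)) <= r:
                    cnt += 1
            total += np.log(cnt / k)
        return total / k

    return phi(m) - phi(m + 1)


def hull_area_bruteforce(points):
    """Monotone-chain convex hull + shoelace area (no scipy)."""
    pts = sorted(set(map(tuple, np.asarray(points, dtype=float))))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def svm_primal_objective(X, y, C, w, b):
    margins = 1.0 - y * (X @ w + b)
    return 0.5 * (w @ w + b * b) + C * np.clip(margins, 0.0, None).sum()
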