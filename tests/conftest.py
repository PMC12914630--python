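import numpy as np
import pytest

from evsecretome import DLSProfile, SampleMetadata


@pytest.fixture
def meta():
    return SampleMetadata(
        sample_id="s1", region="cortex", platform="petri", compartment="dish",
        div=3, condition="pre", timepoint_h=0.0, n_bio=1, n_meas=1,
        cell_seed_density=5e5, collection_interval_days=3.0,
    )


@pytest.fixture
def make_profile(meta):
    def _make(points: dict[float, float], metadata=None) -> DLSProfile:
        radii = np.array(sorted(points))
        counts = np.array([points[r] for r in sorted(points)], dtype=float)
        return DLSProfile(metadata=metadata or meta, grid=radii, count_rate=counts)

    return _make


def exact_mann_whitney_p(a, b) -> tuple[float, float]:
    """Exhaustive-enumeration oracle for the two-sided exact Mann-Whitney p.

    Enumerates every assignment of the pooled (tie-free) values to the two
    groups and returns (U of group a, two-sided p as twice the smaller tail,
    capped at 1). Independent of any library routine.
    """
    from itertools import combinations

    a, b = list(map(float, a)), list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na = len(a)

    def u_of(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_of(a, b)
    us = []
    for idx in combinations(range(len(pooled)), na):
        sel = set(idx)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(u_of(ga, gb))
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return float(u_obs), min(1.0, 2.0 * min(lo, hi))
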