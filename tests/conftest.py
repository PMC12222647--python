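import numpy as np
import pandas as pd
import pytest

from cnasd.io import ArmTable, SegmentProfile
from cnasd.simulate import SimConfig, simulate_cohort, toy_arm_table


@pytest.fixture(scope="session")
def toy_arms() -> ArmTable:
    return toy_arm_table()


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample toy-genome cohort with one planted arm effect."""
    from cnasd.simulate import ArmEffect

    cfg = SimConfig(
        seed=11,
        n_samples=120,
        arm_table="toy",
        alteration_prob=0.25,
        p_broad=0.8,
        arm_effects=[ArmEffect("1p_loss", log_hr=1.0, activation=0.25)],
    )
    return simulate_cohort(cfg)


def make_profile(sample_id, chrom, intervals, default_mean=0.0,
                 arm_span=(0, 3_000_000), nprobes_per_10kb=3.0):
    """Build a single-chromosome profile covering ``arm_span`` with the
    given (start, end, mean) altered intervals and neutral filler."""
    rows = []
    cursor = arm_span[0]
    for start, end, mean in sorted(intervals):
        if start > cursor:
            rows.append((cursor, start, default_mean))
        rows.append((start, end, mean))
        cursor = end
    if cursor < arm_span[1]:
        rows.append((cursor, arm_span[1], default_mean))
    frame = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "nprobes": max(1, int((e - s) * nprobes_per_10kb / 10_000)),
                "mean": m,
                "excluded": False,
            }
            for s, e, m in rows
        ]
    )
    return SegmentProfile(sample_id, frame)


@pytest.fixture
def single_arm_table() -> ArmTable:
    """One chromosome with a 3 Mb p-arm only (q excluded by length)."""
    return ArmTable.from_records(
        [("1", "p", 0, 3_000_000), ("1", "q", 3_500_000, 9_500_000)]
    )


def surv_from_lp(rng, lp, shape=1.2, scale=8.0, censor_max=10.0):
    """Weibull proportional-hazards survival draws for testing."""
    lp = np.asarray(lp, dtype=float)
    u = rng.random(len(lp))
    t = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    c = rng.uniform(0, censor_max, len(lp))
    return np.minimum(t, c), (t <= c).astype(int)
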