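import numpy as np
import pandas as pd
import pytest

from dcgradient import CohortSpec, build_channel_grid, generate_cohort
from dcgradient.grid import default_layout
from dcgradient.signals import HemoglobinTimeSeries


@pytest.fixture(scope="session")
def grid():
    """Default 32-channel analyzed grid (2 hemispheres x 4 streams x 4 levels)."""
    return build_channel_grid()


@pytest.fixture(scope="session")
def full_grid():
    return build_channel_grid(default_layout(full=True))


@pytest.fixture(scope="session")
def mini_grid():
    """Minimal valid layout: 1 stream x 2 levels per hemisphere."""
    a = 3.0
    channels = []
    for hemisphere, sign in (("left", -1.0), ("right", 1.0)):
        for level in (1, 2):
            channels.append(
                {
                    "id": f"{hemisphere[0].upper()}1-{level}",
                    "x": sign * (a / 2 + (level % 2) * a / 2),
                    "y": -(level - 1) * a / 2,
                    "hemisphere": hemisphere,
                    "stream": 1,
                    "level": level,
                }
            )
    return build_channel_grid({"inter_optode_distance_cm": a, "channels": channels})


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec(seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_spec):
    return generate_cohort(cohort_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_hemo(rng, channel_ids, n_samples=400, fs=10.0):
    """Random hemoglobin series with independent HbO/HbR (artifacted-like)."""
    k = len(channel_ids)
    return HemoglobinTimeSeries(
        hbo=rng.standard_normal((k, n_samples)),
        hbr=rng.standard_normal((k, n_samples)),
        channel_ids=list(channel_ids),
        sampling_rate=fs,
    )


def lmm_fixture_table():
    """Deterministic small connection table used for frozen-oracle checks.

    The exact generation sequence matters: Type III F values, dfs and
    the log-likelihood obtained from R's lmerTest/emmeans on this table
    are frozen into the test suite.
    """
    rng = np.random.default_rng(42)
    rows = []
    for pi in range(8):
        dur = rng.normal(10, 4)
        for state in ("ON", "OFF"):
            for stream_id in ("L1", "L2", "R1", "R2"):
                for lp in ("1-2", "2-3"):
                    for d in ("rc", "cr"):
                        rows.append(
                            dict(
                                participant=f"P{pi}",
                                state=state,
                                stream_id=stream_id,
                                level_pair=lp,
                                direction=d,
                                duration_before_implant=dur,
                                dc=0.0,
                            )
                        )
    tab = pd.DataFrame(rows)
    tab["dc"] = 0.2 + 0.1 * (tab.direction == "rc") + rng.normal(0, 0.05, len(tab))
    for _, idx in tab.groupby(["participant", "stream_id"]).groups.items():
        tab.loc[idx, "dc"] += rng.normal(0, 0.03)
    for _, idx in tab.groupby(["participant", "level_pair"]).groups.items():
        tab.loc[idx, "dc"] += rng.normal(0, 0.02)
    return tab


@pytest.fixture(scope="session")
def lmm_table():
    return lmm_fixture_table()
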