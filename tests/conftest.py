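import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hospbench as hb

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def coupled_cohort():
    """One moderate coupled-scenario cohort with long-LOS flags attached."""
    cfg = hb.scenario_preset("coupled", volume_range=(400, 800), seed=11)
    records, effects = hb.generate_cohort(cfg)
    flags, rule = hb.long_los_flags(records)
    return records.assign(long_los=flags.to_numpy()), effects, rule


@pytest.fixture(scope="session")
def coupled_models(coupled_cohort):
    records, _, _ = coupled_cohort
    return hb.fit_casemix_models(records)


@pytest.fixture(scope="session")
def coupled_ratios(coupled_cohort, coupled_models):
    records, _, _ = coupled_cohort
    return hb.standardized_ratios(records, coupled_models)


def tiny_records(n=60, seed=0, n_hospitals=2):
    """Minimal records frame with all cohort columns, for unit tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "hospital_id": [f"H{1 + i % n_hospitals:02d}" for i in range(n)],
            "group": "g1",
            "year": 2010,
            "age_group": pd.Categorical(
                rng.choice(hb.AGE_GROUPS, n), categories=list(hb.AGE_GROUPS),
                ordered=True,
            ),
            "sex": rng.integers(0, 2, n).astype(np.int8),
            "unplanned": rng.integers(0, 2, n).astype(np.int8),
            "transfer_in": rng.integers(0, 2, n).astype(np.int8),
            "urgent_prior": rng.integers(0, 2, n).astype(np.int8),
            "elixhauser_count": rng.poisson(1.5, n),
            "los_days": np.round(rng.lognormal(1.5, 0.5, n), 3),
            "died": rng.integers(0, 2, n).astype(np.int8),
            "readmitted_30d": pd.array(rng.integers(0, 2, n), dtype="Int8"),
        }
    ).assign(
        readmitted_30d=lambda d: d["readmitted_30d"].mask(d["died"] == 1, pd.NA)
    )
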