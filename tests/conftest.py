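import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metaboclass as mc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def processed_cohort(seed: int, effects=None):
    """Generate, normalize, filter to identified analytes, pool subgroups."""
    table, metadata = mc.generate_cohort(mc.GeneratorConfig(seed=seed), effects)
    table = mc.apply_normalizer(table, mc.fit_is_normalizer(table))
    table = mc.filter_features(table)
    metadata = mc.pool_sle_subgroups(metadata)
    return table, metadata


def group_rows(table, metadata, groups):
    by_id = {m.sample_id: (m.pooled_group or m.group) for m in metadata}
    pooled = np.array([by_id[s] for s in table.sample_ids])
    return np.isin(pooled, groups), pooled


@pytest.fixture(scope="session")
def default_cohort():
    """One processed default cohort shared across read-only tests."""
    return processed_cohort(seed=0)


@pytest.fixture(scope="session")
def raw_cohort():
    table, metadata = mc.generate_cohort(mc.GeneratorConfig(seed=0))
    return table, metadata
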