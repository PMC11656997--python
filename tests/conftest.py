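import numpy as np
import pandas as pd
import pytest

import painprofiles as pp


@pytest.fixture(scope="session")
def small_config():
    return pp.GeneratorConfig(n_participants=400, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return pp.generate_cohort(small_config)


@pytest.fixture(scope="session")
def midsize_bundle():
    """Cohort large enough for stable decomposition and association tests."""
    return pp.generate_cohort(pp.GeneratorConfig(n_participants=2500, seed=13))


@pytest.fixture(scope="session")
def midsize_prepared(midsize_bundle):
    b = midsize_bundle
    pain, brain, _ = pp.preprocess_pipeline(
        b.pain_table, b.brain_table, b.confound_table, pp.default_rules(), seed=1
    )
    return b, pain, brain


@pytest.fixture(scope="session")
def midsize_model(midsize_prepared):
    _, pain, brain = midsize_prepared
    return pp.fit_pls(brain, pain, K=6)


def make_feature_table(values, ids=None, **meta_cols):
    """Small helper to build FeatureTables from plain arrays in tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = ids if ids is not None else [f"P{i}" for i in range(n)]
    cols = [f"f{j}" for j in range(m)]
    data = pd.DataFrame(values, index=pd.Index(ids, name="participant_id"), columns=cols)
    meta = pd.DataFrame(
        {
            "domain": meta_cols.get("domain", ["other"] * m),
            "is_location": meta_cols.get("is_location", [False] * m),
            "rule_id": meta_cols.get("rule_id", ["identity"] * m),
        },
        index=data.columns,
    )
    return pp.FeatureTable(data, meta)
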