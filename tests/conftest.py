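import numpy as np
import pytest

import tempocsp as tc


@pytest.fixture(scope="session")
def small_cfg() -> tc.SynthConfig:
    """Compact but well-separated two-class ERD conditions."""
    return tc.SynthConfig(n_trials_per_class=20, seed=7)


@pytest.fixture(scope="session")
def small_ts(small_cfg) -> tc.TrialSet:
    return tc.generate_mi_trialset(small_cfg)


@pytest.fixture(scope="session")
def segments(small_ts):
    return tc.decompose_trialset(small_ts)


@pytest.fixture(scope="session")
def csp_models(segments):
    return [
        tc.fit_csp(s.signals[s.class_indices(1)], s.signals[s.class_indices(2)])
        for s in segments
    ]


@pytest.fixture(scope="session")
def feature_table(csp_models, segments) -> tc.FeatureTable:
    return tc.build_feature_table(csp_models, segments)


def random_feature_table(rng: np.random.Generator, n: int = 60, p: int = 20,
                         signal_cols=(), shift: float = 2.0) -> tc.FeatureTable:
    """Gaussian table with optional class-dependent mean shifts."""
    labels = np.repeat([1, 2], n // 2)
    values = rng.normal(size=(n, p))
    for c in signal_cols:
        values[labels == 2, c] += shift
    provenance = [(j // 4 + 1, j % 4 + 1) for j in range(p)]
    return tc.FeatureTable(values=values, column_provenance=provenance, labels=labels)
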