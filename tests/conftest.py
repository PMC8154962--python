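import numpy as np
import pytest

from dfu_cpr import develop, simulate


@pytest.fixture(scope="session")
def published_score_model():
    """Score model at the published parameters: baseline risk 2.4%, per-point OR 2.57."""
    return develop.score_model_from_published(0.024, 2.57)


@pytest.fixture(scope="session")
def published_risk_table(published_score_model):
    """Published per-score risks with the development score counts."""
    import pandas as pd

    return pd.DataFrame(
        {
            "score": [0, 1, 2, 3, 4],
            "n": simulate.SCORE_COUNTS,
            "probability": [0.024, 0.060, 0.140, 0.292, 0.511],
        }
    )


@pytest.fixture(scope="session")
def register_20k(published_score_model):
    """Self-validation register: 20,000 participants, development score mix,
    outcomes from the published score model."""
    return simulate.simulate_score_register(20_000, seed=7)


@pytest.fixture(scope="session")
def dev_frame_logistic():
    """Pooled development-scale frame with outcomes from the pooled logistic
    model (no between-study heterogeneity), complete cases."""
    from dfu_cpr import harmonize

    cohorts = simulate.simulate_development_suite(31, outcome="logistic", sigma_u=0.0)
    pooled = harmonize.add_history(simulate.pool_cohorts(cohorts))
    frame, _ = harmonize.complete_case_filter(pooled)
    return frame
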