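import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import activebreast as ab

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return ab.CohortSpec(seed=11)


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One default synthetic cohort shared across the session."""
    return ab.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def classifier(default_spec):
    return ab.classifier_signature(default_spec)


@pytest.fixture
def tiny_matrix():
    """A 3-gene x 4-sample TPM matrix with two batches."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 0.0, 5.0],
            "s2": [3.0, 2.0, 0.0],
            "s3": [7.0, 4.0, 1.0],
            "s4": [15.0, 8.0, 2.0],
        },
        index=["gA", "gB", "gC"],
    )
    batch = pd.Series({"s1": "F", "s2": "F", "s3": "P", "s4": "P"})
    return ab.ExpressionMatrix(values, batch, scale="tpm")


def recovery_accuracy(assignments_frame: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Label-agreement accuracy after optimal (global) label matching."""
    merged = assignments_frame.merge(truth, on="sample_id")
    agree = float((merged["label"] == merged["phenotype"]).mean())
    return max(agree, 1.0 - agree)
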