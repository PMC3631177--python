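import numpy as np
import pytest

from anchorsig import ExpressionCohort, SampleMetadata


@pytest.fixture
def small_cohort() -> ExpressionCohort:
    """3 probes x 4 samples, deterministic values around log2 ~ 8."""
    values = np.array(
        [
            [8.0, 8.5, 9.0, 9.5],
            [7.5, 8.0, 8.5, 9.0],
            [8.2, 8.2, 8.2, 8.2],
        ]
    )
    return ExpressionCohort(["p1", "p2", "p3"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def small_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "tumor"),
        SampleMetadata("s2", "tumor"),
        SampleMetadata("s3", "control"),
        SampleMetadata("s4", "control"),
    ]


def make_random_cohort(rng: np.random.Generator, n_probes: int, n_samples: int) -> ExpressionCohort:
    values = 8.0 + rng.standard_normal((n_probes, n_samples))
    return ExpressionCohort(
        [f"p{i}" for i in range(n_probes)],
        [f"s{j}" for j in range(n_samples)],
        values,
    )
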