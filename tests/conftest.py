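import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from zratio.io import ExpressionMatrix, SampleDesign

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20160602)


@pytest.fixture
def design_4x5() -> SampleDesign:
    groups = ["sham", "PHEN", "mTBI", "mTBI_PHEN"]
    assignment = {f"{g}_{k}": g for g in groups for k in range(1, 6)}
    return SampleDesign(assignment, groups)


@pytest.fixture
def small_raw_matrix(rng, design_4x5) -> ExpressionMatrix:
    """12 probes x 20 samples of log-normal intensities, no group effects."""
    n, samples = 12, design_4x5.sample_ids
    log10 = rng.normal(2.5, 0.5, size=(n, len(samples))) + rng.normal(
        0, 0.1, size=(n, len(samples))
    )
    frame = pd.DataFrame(
        10.0**log10,
        index=[f"P{i:03d}" for i in range(1, n + 1)],
        columns=samples,
    )
    return ExpressionMatrix(frame, scale="raw")


@pytest.fixture
def two_group_design() -> SampleDesign:
    assignment = {f"a{k}": "A" for k in range(1, 5)}
    assignment.update({f"b{k}": "B" for k in range(1, 5)})
    return SampleDesign(assignment, ["A", "B"])
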