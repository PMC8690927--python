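import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from iccclust.cohort_io import MutationMatrix

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_matrix(data: dict[str, list], counts=None, samples=None) -> MutationMatrix:
    """Build a MutationMatrix from {gene: [1/0/None per sample]} columns."""
    genes = list(data)
    n = len(next(iter(data.values())))
    if samples is None:
        samples = [f"S{i + 1:03d}" for i in range(n)]
    values = np.full((n, len(genes)), np.nan)
    for j, g in enumerate(genes):
        col = data[g]
        for i, v in enumerate(col):
            if v is not None:
                values[i, j] = v
    status = pd.DataFrame(values, index=samples, columns=genes).astype("Float64").astype("Int8")
    if counts is not None:
        counts = pd.Series(counts, index=samples)
    return MutationMatrix(status, counts)


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized synthetic cohort shared across tests."""
    from iccclust.synthetic_cohort import SyntheticConfig, simulate

    return simulate(SyntheticConfig(n_samples=400, seed=11))
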