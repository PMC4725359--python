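import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dysbiome import AbundanceTable, SampleMeta, meta_from_sample_ids

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_counts() -> AbundanceTable:
    """Hand-written 4-taxa x 4-sample paired counts table (2 subjects)."""
    df = pd.DataFrame(
        {
            "A1N1": [30, 50, 15, 5],
            "A1V1": [40, 40, 10, 10],
            "B1N1": [20, 60, 20, 0],
            "B1V1": [25, 55, 15, 5],
        },
        index=["taxon_a", "taxon_b", "taxon_c", "taxon_d"],
    )
    return AbundanceTable(df, "counts")


@pytest.fixture
def tiny_meta(tiny_counts) -> list[SampleMeta]:
    return meta_from_sample_ids(tiny_counts.samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
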