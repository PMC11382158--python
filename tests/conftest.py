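import pandas as pd
import pytest

from aho.pipeline import classify_records
from aho.synth import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """1,000 synthetic reactions + truth, shared across tests."""
    records, truth = generate(SyntheticConfig(seed=11, n_reactions=1000))
    return records, truth


@pytest.fixture(scope="session")
def classified(small_dataset) -> pd.DataFrame:
    records, truth = small_dataset
    df, excluded = classify_records(records)
    assert not excluded
    return df.merge(truth, on=["record_id", "metal"], suffixes=("", "_true"))
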