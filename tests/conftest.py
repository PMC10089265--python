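import numpy as np
import pandas as pd
import pytest

from invanet.io import (
    CtTable,
    Dataset,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    RANKS,
)
from invanet.panel import default_panel
from invanet.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return generate_dataset(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast small dataset for pipeline-level tests."""
    return generate_dataset(SynthConfig(seed=11, n_sites=10, n_otus=120))


@pytest.fixture()
def tiny_tables():
    """Minimal hand-built tables: 3 samples × 2 OTUs plus metadata."""
    counts = pd.DataFrame(
        [[5, 3], [2, 8], [7, 1]],
        index=["s1", "s2", "s3"],
        columns=["OTU_1", "OTU_2"],
    )
    table = FeatureTable(counts, kind="otu", units="reads")
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            {r: ["unclassified"] * 2 for r in RANKS},
            index=["OTU_1", "OTU_2"],
        )
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "site_id": ["A", "A", "B"],
                "group": ["AP", "N", "AP"],
                "lon": [116.5, 116.5, 117.0],
                "lat": [39.0, 39.0, 39.5],
                "pH": [7.5, 7.6, 7.7],
                "TC": [15.0, 14.0, 16.0],
                "TN": [1.1, 1.2, 1.3],
                "TP": [0.6, 0.7, 0.8],
                "AN": [8.0, 9.0, 10.0],
                "NN": [12.0, 11.0, 13.0],
                "AP": [10.0, 9.0, 11.0],
            },
            index=["s1", "s2", "s3"],
        )
    )
    return table, taxonomy, meta
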