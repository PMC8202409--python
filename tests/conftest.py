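import numpy as np
import pandas as pd
import pytest

from pdacmicro.profiles import (
    RelativeAbundanceTable,
    SampleMetadata,
    TaxonProfileTable,
    Taxonomy,
)
from pdacmicro.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_table() -> TaxonProfileTable:
    counts = pd.DataFrame(
        {
            "s1": [2, 1, 1],
            "s2": [0, 0, 0],
            "s3": [5, 0, 0],
        },
        index=pd.Index(["Bacteroides", "Prevotella", "Mimivirus"]),
    )
    return TaxonProfileTable(counts)


@pytest.fixture
def tiny_taxonomy() -> Taxonomy:
    return Taxonomy(
        pd.DataFrame(
            {
                "phylum": ["Bacteroidetes", "Bacteroidetes", "None"],
                "domain": ["bacteria", "bacteria", "virus"],
            },
            index=pd.Index(["Bacteroides", "Prevotella", "Mimivirus"]),
        )
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "dataset": ["DS1", "DS1", "DS2"],
                "sex": ["male", "female", np.nan],
                "age": [63.0, 70.0, np.nan],
                "sampling_site": ["stroma", "epithelium", "bulk"],
                "tissue_source": ["human_tissue", "human_tissue", "pdx"],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


def rel_from_columns(columns: dict[str, list[float]]) -> RelativeAbundanceTable:
    """Relative-abundance table straight from per-sample columns."""
    frame = pd.DataFrame(columns)
    frame.index = [f"t{i}" for i in range(frame.shape[0])]
    zero = tuple(c for c in frame.columns if frame[c].sum() == 0)
    return RelativeAbundanceTable(frame.astype(float), zero)


@pytest.fixture(scope="session")
def small_study():
    """A fast, fully featured synthetic study (all four cohort archetypes)."""
    config = SyntheticConfig(
        seed=42,
        pool_size=300,
        dataset_sizes=(40, 30, 16, 30),
        zero_read_count=2,
        low_read_count=3,
        reads_mu=float(np.log(2e4)),
    )
    return generate(config)
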