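import numpy as np
import pandas as pd
import pytest

from microcore import (
    CountTable,
    SampleMetadata,
    SimulationConfig,
    TaxonomyTable,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic survey at reduced scale, shared across read-only tests."""
    cfg = SimulationConfig(n_taxa=80, n_samples=30, n_effect_taxa=10, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_table():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(10, 6))
    counts[0] += 5  # guarantee no all-zero sample
    return CountTable(
        counts,
        [f"OTU_{i + 1}" for i in range(10)],
        [f"S{j + 1}" for j in range(6)],
    )


@pytest.fixture
def tiny_taxonomy():
    rows = {}
    for i in range(10):
        rows[f"OTU_{i + 1}"] = {
            "domain": "Bacteria",
            "phylum": f"P{i % 3}",
            "class": "",
            "order": "",
            "family": "",
            "genus": f"G{i}",
        }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture
def simple_metadata():
    data = pd.DataFrame(
        {
            "amendment": ["None", "FYM", "None", "Digestate", "FYM", "None"],
            "farm_id": ["F1", "F1", "F2", "F2", "F3", "F3"],
            "Ca": [2000.0, 2100.0, 1900.0, 2500.0, 2050.0, 1980.0],
            "LOI": [5.0, 6.0, 5.5, 9.0, 6.2, 5.1],
        },
        index=[f"S{j + 1}" for j in range(6)],
    )
    return SampleMetadata(
        data, {"amendment": ("None", "FYM", "Digestate", "Slurry")}
    )
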