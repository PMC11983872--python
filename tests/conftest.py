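import numpy as np
import pandas as pd
import pytest

from microturn import AsvTable, SimulationConfig, simulate_dataset, write_fixture_set


def make_table(counts: dict, taxonomy: dict | None = None, metadata: dict | None = None) -> AsvTable:
    """Small-table constructor for hand-built fixtures.

    ``counts`` maps sample id → {asv: count}. Metadata defaults give every
    sample its own animal, lab source, and day equal to its position.
    """
    counts_df = pd.DataFrame(counts).fillna(0).astype(np.int64)
    asvs = list(counts_df.index)
    samples = list(counts_df.columns)
    tax = pd.DataFrame(
        taxonomy or {}, index=["domain", "phylum", "class", "order", "family", "genus", "species"]
    ).T.reindex(asvs).fillna("")
    meta_defaults = {
        s: {
            "animal_id": f"animal_{s}",
            "group": "g",
            "source": "lab",
            "day": float(i),
            "read_count": int(counts_df[s].sum()),
        }
        for i, s in enumerate(samples)
    }
    if metadata:
        for s, overrides in metadata.items():
            meta_defaults[s].update(overrides)
    meta = pd.DataFrame(meta_defaults).T
    meta.index.name = "sample_id"
    for col in ("day", "read_count"):
        meta[col] = pd.to_numeric(meta[col])
    return AsvTable(counts=counts_df, taxonomy=tax, metadata=meta)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_individuals_per_arm=3,
        pool_size=150,
        core_size={"lab_like": 12, "wild_like": 5},
        transient_size=40,
        depth_range=(8000, 20000),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture_set(small_dataset, d)
    return d
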