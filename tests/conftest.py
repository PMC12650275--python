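import numpy as np
import pandas as pd
import pytest

from gutlink.containers import AsvTable, TaxonomyTable, RANKS


def make_table(counts, groups, sample_ids=None, asv_ids=None) -> AsvTable:
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(counts.shape[0])]
    asv_ids = asv_ids or [f"ASV{j + 1}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=sample_ids, columns=asv_ids, dtype=np.int64)
    return AsvTable(frame, pd.Series(dict(zip(sample_ids, groups))))


def make_taxonomy(asv_to_phylum: dict) -> TaxonomyTable:
    rows = {
        asv: {r: ("Bacteria" if r == "kingdom" else ph if r == "phylum" else "Unassigned")
              for r in RANKS}
        for asv, ph in asv_to_phylum.items()
    }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture
def toy_table() -> AsvTable:
    """Six ASVs over two groups of two samples each."""
    return make_table(
        [[10, 0, 3, 1, 0, 2],
         [8, 1, 2, 0, 0, 3],
         [0, 5, 0, 2, 7, 1],
         [1, 6, 0, 3, 9, 0]],
        ["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def default_synth():
    """One default-design synthetic dataset shared across tests."""
    from gutlink import synthetic

    cfg = synthetic.SynthConfig(seed=11)
    table, tax, truth = synthetic.generate_asv_table(cfg)
    return cfg, table, tax, truth
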