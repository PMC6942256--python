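import numpy as np
import pandas as pd
import pytest

from gutnet import AbundanceTable, generate_ibd_cohort
from gutnet.lineage import lineage_from_labels


def make_table(counts, families, phyla, sample_ids=None, conditions=None,
               study_id="S01"):
    """Small hand-built family-level table for unit tests."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    if conditions is None:
        conditions = ["healthy"] * n_samples
    lineages = [lineage_from_labels(kingdom="Bacteria", phylum=p, family=f)
                for f, p in zip(families, phyla)]
    matrix = pd.DataFrame(counts, index=pd.Index(families, name="taxon"),
                          columns=sample_ids)
    metadata = pd.DataFrame({"study_id": study_id, "condition": conditions},
                            index=pd.Index(sample_ids, name="sample_id"))
    return AbundanceTable(matrix, lineages, metadata)


@pytest.fixture(scope="session")
def ibd_cohort():
    """One simulated CD/UC/healthy cohort (seed 1, 200 samples/condition)."""
    return generate_ibd_cohort(seed=1, n_per_condition=200)


@pytest.fixture
def six_family_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 12))
    counts[:, 0] += 1  # no empty samples
    counts[0] += 1
    return make_table(
        counts,
        families=["F1", "F2", "F3", "G1", "G2", "unclassified"],
        phyla=["P", "P", "P", "Q", "Q", "unclassified"],
        conditions=["CD"] * 6 + ["healthy"] * 6,
    )
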