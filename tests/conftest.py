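import numpy as np
import pandas as pd
import pytest

from lfqdap.model import AbundanceMatrix, Contrast, Dataset, PeptideTable, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, groups, proteins=None, detected=None, sample_ids=None):
    """Convenience constructor for small AbundanceMatrix fixtures."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    feature_ids = np.asarray([f"pep{i}" for i in range(n)], dtype=object)
    if proteins is None:
        proteins = [f"prot{i}" for i in range(n)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(m)]
    return AbundanceMatrix(
        values=values,
        feature_ids=feature_ids,
        sample_ids=np.asarray(sample_ids, dtype=object),
        groups=np.asarray(groups, dtype=object),
        feature_to_protein=np.asarray(proteins, dtype=object),
        detected=detected,
    )


@pytest.fixture
def small_dataset():
    """5 proteins x 4 peptides x 6 samples in two groups, ~10% missing."""
    rng = np.random.default_rng(7)
    rows = []
    samples = [f"s{j}" for j in range(6)]
    for p in range(5):
        for k in range(4):
            for s in samples:
                if rng.random() < 0.1:
                    continue
                rows.append(
                    {
                        "sample_id": s,
                        "protein_id": f"prot{p}",
                        "peptide_id": f"prot{p}_pep{k}",
                        "intensity": float(2 ** rng.normal(20, 1)),
                        "qvalue": 0.001 if rng.random() > 0.2 else 0.05,
                    }
                )
    table = PeptideTable(pd.DataFrame(rows))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["A"] * 3 + ["B"] * 3,
                "exclude": [False, False, True, False, False, False],
            }
        )
    )
    return Dataset(table, meta)


@pytest.fixture
def contrast_ab():
    return Contrast("A_vs_B", "A", "B")
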