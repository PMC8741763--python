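import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import ctag
from ctag.io import CANONICAL_COLUMNS, MutationTable

sys.path.insert(0, str(Path(__file__).parent))  # make the scalar oracle importable


def make_table(rows) -> MutationTable:
    """Build a MutationTable from (sample, gene, type, pos[, ref, alt, score, status, tissue]) tuples."""
    records = []
    for row in rows:
        row = list(row) + [None] * (9 - len(row))
        records.append(
            {
                "sample_id": row[0],
                "gene_id": row[1],
                "mutation_type": row[2],
                "position": row[3],
                "ref_allele": row[4] or "A",
                "alt_allele": row[5] or "T",
                "impact_score": np.nan if row[6] is None else row[6],
                "somatic_status": row[7] or "Confirmed somatic variant",
                "tissue": row[8] or "breast",
            }
        )
    return MutationTable(pd.DataFrame(records, columns=CANONICAL_COLUMNS))


@pytest.fixture(scope="session")
def small_bundle():
    """A small but class-separable cohort for fast pipeline tests."""
    cfg = ctag.CohortConfig(n_tsg=25, n_og=15, n_neutral=80, n_samples=250, seed=7)
    return ctag.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_bundle):
    return ctag.featurize(
        small_bundle.mutations, small_bundle.lengths, scores=small_bundle.scores
    )


@pytest.fixture(scope="session")
def small_ensemble(small_bundle, small_matrix):
    """A quickly trained ensemble (3 stability seeds) on the small cohort."""
    return ctag.train_ensemble(
        small_matrix, small_bundle.label_set(), n_seeds=3, master_seed=5
    )
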