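from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refstab.ct_data import CtTable, SAMPLE_LEVELS


def make_ct_frame(genes, samples, values) -> pd.DataFrame:
    """Gene x sample frame with a (treatment, timepoint, replicate) column index."""
    cols = pd.MultiIndex.from_tuples(samples, names=SAMPLE_LEVELS)
    return pd.DataFrame(np.asarray(values, dtype=float), index=pd.Index(genes, name="gene"), columns=cols)


def make_condition_frame(genes, n_samples, values, treatment="T") -> pd.DataFrame:
    """Aggregated-style frame: columns are (treatment, timepoint) conditions."""
    cols = pd.MultiIndex.from_tuples(
        [(treatment, float(i)) for i in range(n_samples)], names=("treatment", "timepoint")
    )
    return pd.DataFrame(np.asarray(values, dtype=float), index=pd.Index(genes, name="gene"), columns=cols)


def random_condition_frame(rng, n_genes=6, n_samples=12, loc=20.0, scale=1.0) -> pd.DataFrame:
    genes = [f"G{i:02d}" for i in range(n_genes)]
    values = loc + scale * rng.standard_normal((n_genes, n_samples))
    return make_condition_frame(genes, n_samples, values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240902)


@pytest.fixture
def small_table() -> CtTable:
    """2 genes x (1 treatment, 2 timepoints, 3 replicates)."""
    samples = [("Ctl", 0.0, r) for r in (1, 2, 3)] + [("Ctl", 3.0, r) for r in (1, 2, 3)]
    values = [[20.0, 20.2, 20.4, 21.0, 21.1, 20.9],
              [18.0, 18.1, 17.9, 18.0, 18.2, 17.8]]
    return CtTable(make_ct_frame(["gA", "gB"], samples, values))
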