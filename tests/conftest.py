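"""Shared fixtures: small hand-built tables and reusable synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import paircoda as pc
from paircoda.io import CountTable


@pytest.fixture
def tiny_table() -> CountTable:
    counts = pd.DataFrame(
        {
            "s1": [5, 0, 3],
            "s2": [1, 2, 0],
        },
        index=pd.Index(["taxA", "taxB", "taxC"], name="taxon_id"),
    )
    lineages = pd.Series(
        [
            "d__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G1;s__SpA",
            "d__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G1;s__SpB",
            "d__Bacteria;p__P2;c__C2;o__O2;f__F2;g__G2;s__SpC",
        ],
        index=counts.index,
    )
    return CountTable(counts, lineages)


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "patient_id": ["p1", "p1"],
            "sample_type": ["stool", "biopsy"],
            "batch": ["B1", "B1"],
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """24-patient, 60-taxon cohort with the default planted truth."""
    truth = pc.default_truth(n_taxa=60, seed=3)
    table, meta, truth = pc.generate_cohort(24, truth, seed=42)
    return table, meta, truth


@pytest.fixture(scope="session")
def random_compositions():
    rng = np.random.default_rng(11)
    values = rng.dirichlet(np.ones(8) * 2, size=20)
    return pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(20)],
        columns=[f"t{i}" for i in range(8)],
    )
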