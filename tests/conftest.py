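"""Shared fixtures: synthetic cohorts and generated file fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plasmaprofiler import preprocess
from plasmaprofiler.model import IntensityMatrix, make_sample_table
from plasmaprofiler.simulate import CohortConfig, emit_fixture_suite, generate_cohort

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """One full-design synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_agg(default_cohort):
    matrix = preprocess.remove_flagged_proteins(default_cohort.matrix)
    return preprocess.aggregate_replicates(matrix)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Deterministic file fixtures written by the synthetic module."""
    outdir = tmp_path_factory.mktemp("fixtures")
    emit_fixture_suite(outdir)
    return outdir


def build_matrix(values: dict, samples: list[tuple], genes: dict | None = None):
    """Small IntensityMatrix from {accession: [per-run linear values]}.

    ``samples`` is a list of (run_label, individual, week, replicate).
    """
    sample_df = make_sample_table(
        pd.DataFrame(
            samples, columns=["run_label", "individual_id", "week", "replicate"]
        )
    )
    vals = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    vals.columns = sample_df.index
    vals.index.name = "accession"
    genes = genes or {}
    proteins = pd.DataFrame(
        {
            "gene_symbol": [genes.get(a, a) for a in vals.index],
            "is_contaminant": False,
            "is_reverse": False,
        },
        index=vals.index,
    )
    return IntensityMatrix(values=vals, proteins=proteins, samples=sample_df)


def build_agg(values: dict, individuals: list[str], weeks: list[int],
              genes: dict | None = None):
    """Small AggregatedMatrix from {accession: {(individual, week): log2}}."""
    from plasmaprofiler.model import AggregatedMatrix

    cols = pd.MultiIndex.from_product(
        [individuals, weeks], names=["individual_id", "week"]
    )
    data = pd.DataFrame(np.nan, index=list(values), columns=cols)
    for acc, cells in values.items():
        for key, v in cells.items():
            data.loc[acc, key] = v
    data.index.name = "accession"
    genes = genes or {}
    proteins = pd.DataFrame(
        {
            "gene_symbol": [genes.get(a, a) for a in data.index],
            "is_contaminant": False,
            "is_reverse": False,
        },
        index=data.index,
    )
    counts = data.notna().astype(int)
    return AggregatedMatrix(values=data, counts=counts, proteins=proteins)
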