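"""Cleaning, replicate aggregation and completeness filtering."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import build_matrix
from plasmaprofiler import preprocess
from plasmaprofiler.model import MAINTENANCE_WEEKS, ValidationError
from plasmaprofiler.simulate import CohortConfig, generate_cohort


def test_remove_flagged_counts():
    samples = [("R1", "P01", -8, 1)]
    m = build_matrix({f"A{i}": [10.0] for i in range(10)}, samples)
    m.proteins.loc[["A0", "A1"], "is_contaminant"] = True
    cleaned = preprocess.remove_flagged_proteins(m)
    assert cleaned.n_proteins == 8
    # no flags -> identity
    again = preprocess.remove_flagged_proteins(cleaned)
    pd.testing.assert_frame_equal(again.values, cleaned.values)


def test_aggregation_examples():
    samples = [(f"R{r}", "P01", -8, r) for r in range(1, 5)]
    m = build_matrix(
        {
            "CONST": [2.0**2] * 4,
            "SKEWED": [2.0**1, 2.0**2, 2.0**3, 2.0**10],
        },
        samples,
    )
    med = preprocess.aggregate_replicates(m, method="median")
    assert med.values.loc["CONST"].iloc[0] == pytest.approx(2.0)
    assert med.values.loc["SKEWED"].iloc[0] == pytest.approx(2.5)
    mean = preprocess.aggregate_replicates(m, method="mean")
    assert mean.values.loc["SKEWED"].iloc[0] == pytest.approx(4.0)
    assert med.counts.loc["SKEWED"].iloc[0] == 4


def test_zero_noise_aggregate_reconstructs_planted_surface():
    cfg = CohortConfig(
        n_individuals=3, n_dropouts=0, n_proteins=8, seed=2,
        include_roster=False, sigma_w=0.0, sigma_t_range=(0.0, 0.0),
        missing_alpha=-50.0, n_planted_specific=0, n_lysis_runs=0,
        n_coagulation_runs=0, n_non_improvers=0, clinical_links={},
    )
    cohort = generate_cohort(cfg)
    agg = preprocess.aggregate_replicates(cohort.matrix)
    truth = cohort.truth
    from plasmaprofiler.simulate import ARCHETYPE_SHAPES, WEEKS

    for acc in agg.values.index:
        row = truth.proteins.loc[acc]
        g = ARCHETYPE_SHAPES[row["archetype"]]
        for (ind, week) in agg.values.columns:
            expected = (
                row["mu_log2"]
                + truth.offsets.loc[acc, ind]
                + row["delta_log2"] * g[WEEKS.index(week)]
            )
            assert agg.values.loc[acc, (ind, week)] == pytest.approx(expected)


def _toy_completeness_matrix():
    """6 proteins x 2 individuals x 5 maintenance weeks with holes."""
    rng = np.random.default_rng(0)
    samples = [
        (f"{ind}_w{w}_r1", ind, w, 1)
        for ind in ("P01", "P02")
        for w in MAINTENANCE_WEEKS
    ]
    observed = {
        "FULL_ONE": {("P01", w) for w in MAINTENANCE_WEEKS},
        "FULL_BOTH": {(i, w) for i in ("P01", "P02") for w in MAINTENANCE_WEEKS},
        "MISS_26": {(i, w) for i in ("P01", "P02") for w in MAINTENANCE_WEEKS}
        - {("P01", 26), ("P02", 26)},
        "SPLIT": {("P01", w) for w in (4, 13, 26)} | {("P02", w) for w in (39, 52)},
        "EMPTY": set(),
        "FULL_P02": {("P02", w) for w in MAINTENANCE_WEEKS},
    }
    values = {}
    for acc, cells in observed.items():
        row = []
        for _, ind, w, _ in samples:
            row.append(float(rng.uniform(5, 10)) if (ind, w) in cells else 0.0)
        values[acc] = row
    m = build_matrix({k: [v if v > 0 else np.nan for v in vals]
                      for k, vals in values.items()}, samples)
    return m, observed


def test_maintenance_filter_matches_brute_force():
    m, observed = _toy_completeness_matrix()
    agg = preprocess.aggregate_replicates(m)
    result = set(preprocess.filter_maintenance_complete(agg))
    # independent brute-force enumeration over (protein, individual)
    expected = {
        acc
        for acc, cells in observed.items()
        if any(
            all((ind, w) in cells for w in MAINTENANCE_WEEKS)
            for ind in ("P01", "P02")
        )
    }
    assert result == expected == {"FULL_ONE", "FULL_BOTH", "FULL_P02"}


def test_maintenance_filter_requires_weeks():
    samples = [("R1", "P01", -8, 1)]
    m = build_matrix({"A": [4.0]}, samples)
    agg = preprocess.aggregate_replicates(m)
    with pytest.raises(ValidationError):
        preprocess.filter_maintenance_complete(agg)


def test_maintenance_filter_monotone_in_observations():
    """Adding an observation never removes a protein from the result."""
    m, observed = _toy_completeness_matrix()
    agg = preprocess.aggregate_replicates(m)
    before = set(preprocess.filter_maintenance_complete(agg))
    filled = m.values.fillna(100.0)
    m2 = build_matrix(
        {acc: filled.loc[acc].tolist() for acc in filled.index},
        [(r, *m.samples.loc[r]) for r in m.samples.index],
    )
    after = set(
        preprocess.filter_maintenance_complete(preprocess.aggregate_replicates(m2))
    )
    assert before <= after


def test_aggregation_commutes_with_protein_subsetting(default_cohort):
    m = default_cohort.matrix
    subset = list(m.values.index[:20])
    a = preprocess.aggregate_replicates(m.subset_proteins(subset))
    b = preprocess.aggregate_replicates(m)
    pd.testing.assert_frame_equal(a.values, b.values.loc[subset])
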