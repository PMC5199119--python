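"""Protein-clinical correlation: pairing, Pearson r, BH across proteins."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import build_agg
from plasmaprofiler import clinical as clin_mod
from plasmaprofiler.model import ClinicalTable, NotEvaluableError
from plasmaprofiler.simulate import CohortConfig, generate_cohort


def _clinical(values: dict) -> ClinicalTable:
    idx = pd.MultiIndex.from_tuples(values.keys(), names=["individual_id", "week"])
    return ClinicalTable(data=pd.DataFrame({"BMI": list(values.values())}, index=idx))


def test_paired_observation_count():
    inds = [f"P{i:02d}" for i in range(40)]
    weeks = [-8, 0, 52]
    vals = {"A": {(i, w): 20.0 + k for k, (i, w) in
                  enumerate((i, w) for i in inds for w in weeks)}}
    agg = build_agg(vals, inds, weeks)
    table = _clinical({(i, w): 30.0 for i in inds for w in weeks})
    pairs = clin_mod.paired_observations(agg, table, "BMI", "A")
    assert len(pairs) == 120


def test_missing_protein_not_evaluable():
    agg = build_agg({"A": {}}, ["P01"], [-8, 0, 52])
    table = _clinical({("P01", w): 30.0 for w in (-8, 0, 52)})
    with pytest.raises(NotEvaluableError):
        clin_mod.paired_observations(agg, table, "BMI", "A")


def test_pairing_matches_bruteforce_enumeration():
    inds = ["P01", "P02", "P03"]
    weeks = [-8, 0, 52]
    rng = np.random.default_rng(0)
    prot = {}
    for i in inds:
        for w in weeks:
            if rng.random() > 0.3:
                prot[(i, w)] = float(rng.uniform(20, 25))
    clinv = {}
    for i in inds:
        for w in weeks:
            if rng.random() > 0.3:
                clinv[(i, w)] = float(rng.uniform(28, 40))
    agg = build_agg({"A": prot}, inds, weeks)
    table = _clinical(clinv)
    expected_keys = sorted(set(prot) & set(clinv))
    pairs = clin_mod.paired_observations(agg, table, "BMI", "A", min_n=1)
    assert sorted(pairs.index) == expected_keys


def test_pearson_hand_oracle():
    """Closed-form sums on {(1,2),(2,1),(3,4),(4,3),(5,5)} -> r=0.8, p from t3."""
    inds = [f"P{i:02d}" for i in range(5)]
    x = [1, 2, 3, 4, 5]
    y = [2, 1, 4, 3, 5]
    agg = build_agg({"A": {(i, 0): float(v) for i, v in zip(inds, x)}}, inds, [0])
    table = _clinical({(i, 0): float(v) for i, v in zip(inds, y)})
    out = clin_mod.correlate_all(agg, table, "BMI", min_n=3)
    assert out.loc["A", "r"] == pytest.approx(0.8, rel=1e-9)
    assert out.loc["A", "p"] == pytest.approx(0.1040880387, rel=1e-6)
    assert out.loc["A", "n"] == 5


def test_exact_linear_relation():
    inds = [f"P{i:02d}" for i in range(12)]
    agg = build_agg({"A": {(i, 0): 20.0 + k for k, i in enumerate(inds)}}, inds, [0])
    table = _clinical({(i, 0): 5.0 + 2.0 * k for k, i in enumerate(inds)})
    out = clin_mod.correlate_all(agg, table, "BMI")
    assert out.loc["A", "r"] == pytest.approx(1.0)
    assert out.loc["A", "p"] < 1e-12


def test_r_invariant_under_positive_affine_transforms():
    rng = np.random.default_rng(2)
    inds = [f"P{i:02d}" for i in range(15)]
    xs = rng.normal(22, 1, 15)
    ys = 0.5 * xs + rng.normal(0, 0.5, 15)
    agg1 = build_agg({"A": {(i, 0): float(v) for i, v in zip(inds, xs)}}, inds, [0])
    agg2 = build_agg(
        {"A": {(i, 0): float(3.0 * v + 7.0) for i, v in zip(inds, xs)}}, inds, [0]
    )
    t1 = _clinical({(i, 0): float(v) for i, v in zip(inds, ys)})
    t2 = _clinical({(i, 0): float(0.1 * v + 50.0) for i, v in zip(inds, ys)})
    r1 = clin_mod.correlate_all(agg1, t1, "BMI").loc["A", "r"]
    r2 = clin_mod.correlate_all(agg2, t2, "BMI").loc["A", "r"]
    assert r1 == pytest.approx(r2, rel=1e-9)


def test_zero_variance_not_evaluable():
    inds = [f"P{i:02d}" for i in range(12)]
    agg = build_agg({"A": {(i, 0): 21.0 for i in inds}}, inds, [0])
    table = _clinical({(i, 0): 30.0 + k for k, i in enumerate(inds)})
    out = clin_mod.correlate_all(agg, table, "BMI")
    assert np.isnan(out.loc["A", "r"])
    assert not out.loc["A", "significant"]


def test_planted_link_recovered_within_sampling_band():
    """A planted r=0.5 link at n=120 lands in the analytic band [0.35, 0.62]."""
    cfg = CohortConfig(
        n_individuals=40, n_dropouts=0, n_proteins=30, seed=21,
        include_roster=False, archetype_probs={"null": 1.0},
        n_planted_specific=0, n_lysis_runs=0, n_coagulation_runs=0,
        n_non_improvers=0, burden_fraction=0.0,
        clinical_links={"HOMA-IR": (("PROT0003", 0.5),)},
    )
    cohort = generate_cohort(cfg)
    from plasmaprofiler import preprocess

    agg = preprocess.aggregate_replicates(cohort.matrix)
    out = clin_mod.correlate_all(agg, cohort.clinical, "HOMA-IR")
    acc = cohort.truth.proteins.index[
        cohort.truth.proteins["gene_symbol"] == "PROT0003"
    ][0]
    assert out.loc[acc, "n"] == 120
    assert 0.35 <= out.loc[acc, "r"] <= 0.62
    assert out.loc[acc, "significant"]


def test_null_variable_controls_false_positives():
    """An unlinked variable yields ~5% raw p<0.05 and ~no BH discoveries."""
    cfg = CohortConfig(
        n_individuals=40, n_dropouts=0, n_proteins=200, seed=6,
        include_roster=False, archetype_probs={"null": 1.0},
        n_planted_specific=0, n_lysis_runs=0, n_coagulation_runs=0,
        n_non_improvers=0, burden_fraction=0.0, clinical_links={},
    )
    cohort = generate_cohort(cfg)
    from plasmaprofiler import preprocess

    agg = preprocess.aggregate_replicates(cohort.matrix)
    out = clin_mod.correlate_all(agg, cohort.clinical, "glucose")
    raw = (out["p"] < 0.05).mean()
    assert 0.0 <= raw <= 0.12
    assert out["significant"].mean() <= 0.02
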