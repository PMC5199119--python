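"""GO-level aggregation of apolipoprotein trajectories; APOB/APOA1 ratio."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import build_agg
from plasmaprofiler import lipoproteins
from plasmaprofiler.model import AnnotationTable, NotEvaluableError, WEEKS
from plasmaprofiler.reference import PARTICLE_TERMS, roster_annotation_frame


@pytest.fixture(scope="module")
def annotations():
    return AnnotationTable(data=roster_annotation_frame())


def _z_frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(WEEKS))


def test_single_member_particle_equals_member_profile(annotations):
    z = _z_frame({"LPA": np.linspace(-1, 1, 7), "APOB": np.linspace(1, -1, 7)})
    out = lipoproteins.particle_profiles(z, annotations, particles=("LDL",))
    ldl = out[0]
    assert set(ldl.members) == {"APOB", "LPA"}
    # mirror-image members cancel to a flat aggregate
    assert np.allclose(ldl.profile, 0.0)


def test_particle_aggregation_matches_bruteforce(annotations, default_agg):
    from plasmaprofiler import trajectories

    med = trajectories.median_profiles(default_agg)
    med.index = default_agg.proteins.loc[med.index, "gene_symbol"]
    z = trajectories.zscored_profiles(med).dropna()
    out = lipoproteins.particle_profiles(z, annotations)
    by_term = {p.term: p for p in out}
    assert set(by_term) == set(PARTICLE_TERMS)
    for particle, profile in by_term.items():
        term = PARTICLE_TERMS[particle]
        members = [
            g for g in annotations.genes_with_term("gocc", term) if g in z.index
        ]
        assert sorted(members) == list(profile.members)
        expected = z.loc[members].mean(axis=0)
        pd.testing.assert_series_equal(profile.profile, expected)


def test_particle_aggregation_commutes_with_member_order(annotations):
    z1 = _z_frame({"APOB": np.arange(7.0), "APOE": np.ones(7), "LPA": -np.arange(7.0)})
    z2 = z1.loc[["LPA", "APOE", "APOB"]]
    a = lipoproteins.particle_profiles(z1, annotations, particles=("LDL",))[0]
    b = lipoproteins.particle_profiles(z2, annotations, particles=("LDL",))[0]
    assert a.members == b.members
    pd.testing.assert_series_equal(a.profile, b.profile)


def test_missing_particle_dropped(annotations):
    z = _z_frame({"CRP": np.ones(7)})
    out = lipoproteins.particle_profiles(z, annotations, particles=("HDL",))
    assert out == []


def test_gobp_keyword_matching(annotations):
    z = _z_frame(
        {g: np.ones(7) for g in ("APOA1", "APOB", "APOC2", "CRP", "HBB")}
    )
    out = lipoproteins.gobp_keyword_profiles(z, annotations)
    terms = {p.term for p in out}
    assert "lipid metabolic process" in terms
    assert "cholesterol transport" in terms
    # matched on the "fat" keyword as a substring
    assert "fatty acid metabolic process" in terms
    assert "acute-phase response" not in terms
    assert "oxygen transport" not in terms
    # brute-force filter agrees
    expected = {
        t
        for t in annotations.terms("gobp")
        if any(k in t.lower() for k in ("lipid", "lipoprotein", "fat", "cholesterol"))
        and any(g in z.index for g in annotations.genes_with_term("gobp", t))
    }
    assert terms == expected


def test_gobp_no_matches_is_empty(annotations):
    z = _z_frame({"CRP": np.ones(7)})
    out = lipoproteins.gobp_keyword_profiles(z, annotations, keywords=("ribosome",))
    assert out == []


def _ratio_agg(apob_factor=1.0):
    weeks = list(WEEKS)
    vals = {
        "APOB": {("P01", w): np.log2(800.0 * (apob_factor if w >= 0 else 1.0))
                 for w in weeks},
        "APOA1": {("P01", w): np.log2(800.0) for w in weeks},
    }
    return build_agg(vals, ["P01"], weeks)


def test_ratio_examples():
    out = lipoproteins.apob_apoa1_ratio(_ratio_agg(), "P01")
    assert np.allclose(out["ratio"], 1.0)
    assert np.allclose(out["percent_change"], 0.0)
    halved = lipoproteins.apob_apoa1_ratio(_ratio_agg(apob_factor=0.5), "P01")
    assert halved.loc[0, "percent_change"] == pytest.approx(-50.0)
    assert halved.loc[-8, "percent_change"] == pytest.approx(0.0)


def test_ratio_missing_week_skipped():
    agg = _ratio_agg()
    agg.values.loc["APOB", ("P01", 13)] = np.nan
    out = lipoproteins.apob_apoa1_ratio(agg, "P01")
    assert 13 not in out.index


def test_ratio_invariant_to_run_calibration_factor():
    """A common multiplicative factor on a whole run cancels in the ratio."""
    agg1 = _ratio_agg(apob_factor=0.8)
    agg2 = _ratio_agg(apob_factor=0.8)
    agg2.values[("P01", 26)] += np.log2(3.0)  # recalibrate one sample
    r1 = lipoproteins.apob_apoa1_ratio(agg1, "P01")
    r2 = lipoproteins.apob_apoa1_ratio(agg2, "P01")
    pd.testing.assert_frame_equal(r1, r2)


def test_cohort_ratio_recovers_planted_shift(default_agg):
    """APOB -10% vs APOA1 -2% plants an ~-8% sustained ratio change."""
    out = lipoproteins.cohort_apob_apoa1(default_agg)
    sustained = out.loc[[0, 4, 13, 26, 39, 52], "median_percent_change"].mean()
    assert sustained == pytest.approx(-8.2, abs=3.0)
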