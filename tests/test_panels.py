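"""Panel construction, per-individual scoring, IR panels, burden groups."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import build_agg
from plasmaprofiler import io, panels
from plasmaprofiler.model import (
    AnnotationTable,
    NotEvaluableError,
    ValidationError,
    WEEKS,
)
from plasmaprofiler.panels import EmptyPanelError
from plasmaprofiler.reference import (
    BMI_PANEL_GENES,
    INFLAMMATION_ADDED_GENES,
    INFLAMMATION_KEYWORD_GENES,
    TOP_BMI_GENES,
    roster_annotation_frame,
)


@pytest.fixture(scope="module")
def reference_annotations():
    return AnnotationTable(data=roster_annotation_frame())


def test_inflammation_set_worked_example(reference_annotations):
    """23 keyword hits (C1Q collapsed) -> remove CD14, add APCS+LBP -> 24."""
    highly_significant = set(INFLAMMATION_KEYWORD_GENES) | {"SERPINF1", "APOB"}
    panel = panels.build_inflammation_set(highly_significant, reference_annotations)
    assert len(panel.members) == 24
    assert "C1Q" in panel.members
    assert "CD14" not in panel.members
    assert set(INFLAMMATION_ADDED_GENES) <= set(panel.members)
    # keyword filter itself matched 23 entries with C1Q counted once
    keyword_hits = {
        g for g in reference_annotations.genes_with_any_keyword(
            ("acute phase", "inflammatory response", "immunity")
        )
        if g in highly_significant
    }
    assert len(keyword_hits) - 2 == 23  # three C1Q chains -> one entry


def test_inflammation_set_idempotent_and_order_independent(reference_annotations):
    hs = list(INFLAMMATION_KEYWORD_GENES)
    a = panels.build_inflammation_set(set(hs), reference_annotations)
    b = panels.build_inflammation_set(set(reversed(hs)), reference_annotations)
    assert a.members == b.members
    again = panels.build_inflammation_set(set(a.members), reference_annotations)
    assert set(INFLAMMATION_ADDED_GENES) <= set(again.members)


def test_inflammation_set_edge_cases(reference_annotations):
    only_added = panels.build_inflammation_set(set(), reference_annotations)
    assert set(only_added.members) == {"APCS", "LBP"}
    unchanged = panels.build_inflammation_set(
        {"CRP"}, reference_annotations, remove=("NOT_PRESENT",), add=()
    )
    assert unchanged.members == ("CRP",)


def test_protein_slope_examples():
    assert panels.protein_slope([0, 1, 2], [5.0, 5.0, 5.0]) == pytest.approx(0.0)
    assert panels.protein_slope([0, 1, 2], [0.0, 1.0, 2.0]) == pytest.approx(1.0)
    # frozen closed-form oracle: sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)
    assert panels.protein_slope(
        [0, 13, 26, 52], [1.0, 2.0, 2.0, 4.0]
    ) == pytest.approx(0.0549450549, rel=1e-8)
    with pytest.raises(NotEvaluableError):
        panels.protein_slope([0, 1], [1.0, 2.0])


def test_select_bmi_panel_from_reference_fixture(fixture_dir, reference_annotations):
    corr = pd.read_csv(fixture_dir / "bmi_correlations_reference.tsv", sep="\t")
    inflammation = panels.build_inflammation_set(
        set(INFLAMMATION_KEYWORD_GENES), reference_annotations
    )
    ten = panels.select_bmi_panel(inflammation, corr)
    assert len(ten.members) == 10
    assert set(ten.members) == set(BMI_PANEL_GENES)
    # the five most significant correlates come first, in fixture order
    assert ten.members[:5] == TOP_BMI_GENES


def test_select_bmi_panel_empty_and_singleton(reference_annotations):
    inflammation = panels.build_inflammation_set(
        set(INFLAMMATION_KEYWORD_GENES), reference_annotations
    )
    none_sig = pd.DataFrame(
        {"gene_symbol": ["CRP"], "r": [0.3], "p": [0.2], "significant": [False]}
    )
    with pytest.raises(EmptyPanelError):
        panels.select_bmi_panel(inflammation, none_sig)
    one = pd.DataFrame(
        {"gene_symbol": ["CRP"], "r": [0.3], "p": [1e-6], "significant": [True]}
    )
    assert panels.select_bmi_panel(inflammation, one).members == ("CRP",)


def _panel_agg(trend=-0.1, members=("CRP", "SAA1"), individual="P01"):
    weeks = list(WEEKS)
    vals = {}
    for k, g in enumerate(members):
        vals[g] = {
            (individual, w): 20.0 + k + trend * (i + 1)
            for i, w in enumerate(weeks)
        }
    return build_agg(vals, [individual], weeks)


def test_individual_profile_decreasing_members_benefit():
    agg = _panel_agg(trend=-0.1)
    panel = panels.PanelDefinition("toy", ("CRP", "SAA1"))
    prof = panels.individual_panel_profile(agg, panel, "P01")
    assert prof.slope < 0
    assert prof.benefit


def test_individual_profile_constant_members_no_benefit():
    agg = _panel_agg(trend=0.0)
    panel = panels.PanelDefinition("toy", ("CRP", "SAA1"))
    prof = panels.individual_panel_profile(agg, panel, "P01")
    assert prof.slope == pytest.approx(0.0, abs=1e-12)
    assert not prof.benefit


def test_panel_slope_invariant_to_member_affine_rescaling():
    agg1 = _panel_agg(trend=-0.1)
    agg2 = _panel_agg(trend=-0.1)
    agg2.values.loc["CRP"] = agg2.values.loc["CRP"] * 4.0 + 3.0
    panel = panels.PanelDefinition("toy", ("CRP", "SAA1"))
    p1 = panels.individual_panel_profile(agg1, panel, "P01")
    p2 = panels.individual_panel_profile(agg2, panel, "P01")
    assert p1.slope == pytest.approx(p2.slope, rel=1e-9)


def test_build_ir_panels_rank_oracle(reference_annotations):
    rows = []
    for k in range(4):
        rows.append((f"POS{k}", 0.6 - 0.05 * k, 1e-8 * (k + 1), True))
    for k in range(5):
        rows.append((f"NEG{k}", -0.6 + 0.05 * k, 1e-8 * (k + 1), True))
    rows.append(("WEAKPOS", 0.2, 0.04, True))
    rows.append(("NULL", 0.01, 0.9, False))
    corr = pd.DataFrame(rows, columns=["gene_symbol", "r", "p", "significant"])
    pro, anti = panels.build_ir_panels(corr, reference_annotations)
    assert pro.members == ("POS0", "POS1", "POS2", "POS3")
    assert anti.members == ("NEG0", "NEG1", "NEG2", "NEG3", "NEG4")
    assert anti.orientation_of("NEG0") == -1


def test_build_ir_panels_excludes_immunoglobulins(reference_annotations):
    rows = [("IGHG1", 0.7, 1e-12, True)]
    rows += [(f"POS{k}", 0.5, 1e-6, True) for k in range(4)]
    rows += [(f"NEG{k}", -0.5, 1e-6, True) for k in range(5)]
    corr = pd.DataFrame(rows, columns=["gene_symbol", "r", "p", "significant"])
    pro, _ = panels.build_ir_panels(corr, reference_annotations)
    assert "IGHG1" not in pro.members


def test_build_ir_panels_tie_break_by_abs_r_then_symbol(reference_annotations):
    rows = [
        ("BBB", 0.30, 1e-4, True),
        ("AAA", 0.30, 1e-4, True),
        ("CCC", 0.50, 1e-4, True),
        ("DDD", -0.40, 1e-4, True),
    ]
    corr = pd.DataFrame(rows, columns=["gene_symbol", "r", "p", "significant"])
    pro, anti = panels.build_ir_panels(corr, reference_annotations, k_pos=2, k_neg=1)
    assert pro.members == ("CCC", "AAA")
    assert anti.members == ("DDD",)


def test_benefit_fraction_near_half_on_null_cohort():
    """With no planted effects the slope sign is a fair coin."""
    from plasmaprofiler import preprocess
    from plasmaprofiler.simulate import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_individuals=40, n_dropouts=0, n_proteins=12, seed=17,
        include_roster=False, archetype_probs={"null": 1.0},
        n_planted_specific=0, n_lysis_runs=0, n_coagulation_runs=0,
        n_non_improvers=0, burden_fraction=0.0, clinical_links={},
    )
    cohort = generate_cohort(cfg)
    agg = preprocess.aggregate_replicates(cohort.matrix)
    panel = panels.PanelDefinition(
        "null", tuple(cohort.matrix.proteins["gene_symbol"][:10])
    )
    ben = panels.benefit_table(agg, panel)
    assert 0.25 <= ben["benefit"].mean() <= 0.75


def test_benefit_recovers_planted_improvers(default_cohort, default_agg):
    truth = default_cohort.truth.individuals
    panel = panels.PanelDefinition("infl", ("CRP", "SAA1", "SAA4", "ORM1", "ORM2",
                                            "CFH", "C3", "CFI", "CFB", "ATRN"))
    ben = panels.benefit_table(default_agg, panel)
    merged = ben.join(truth)
    agreement = (merged["benefit"] == merged["improver"]).mean()
    assert agreement >= 0.9


def test_stratify_burden_recovers_planted_groups(default_cohort, default_agg):
    truth = default_cohort.truth.individuals
    infl = panels.PanelDefinition("infl", ("CRP", "SAA1", "SAA4", "ORM2", "CFH",
                                           "C3", "CFI", "CFB", "ATRN", "APCS"))
    pro = panels.PanelDefinition(
        "pro", ("SERPINF1", "FETUB", "PRG4", "SERPIND1"),
        orientation=tuple((m, 1) for m in ("SERPINF1", "FETUB", "PRG4", "SERPIND1")),
    )
    anti_members = ("ADIPOQ", "NRP1", "APOF", "SHBG", "GC")
    anti = panels.PanelDefinition(
        "anti", anti_members, orientation=tuple((m, -1) for m in anti_members)
    )
    strat = panels.stratify_burden(default_agg, infl, pro, anti)
    # set identity: the burden group is the intersection
    assert (strat["high_burden"] == (strat["high_IR"] & strat["high_inflammation"])).all()
    completers = truth[truth["completer"]]
    merged = strat.join(completers, rsuffix="_truth")
    agreement = (merged["high_burden"] == merged["high_burden_truth"]).mean()
    assert agreement >= 0.85


def test_stratify_identical_individuals_degenerate():
    weeks = list(WEEKS)
    inds = [f"P{i:02d}" for i in range(6)]
    vals = {
        g: {(i, w): 20.0 for i in inds for w in weeks} for g in ("CRP", "ADIPOQ", "PRG4")
    }
    agg = build_agg(vals, inds, weeks)
    infl = panels.PanelDefinition("i", ("CRP",))
    pro = panels.PanelDefinition("p", ("PRG4",))
    anti = panels.PanelDefinition("a", ("ADIPOQ",), orientation=(("ADIPOQ", -1),))
    strat = panels.stratify_burden(agg, infl, pro, anti)
    assert strat["degenerate_split"].all()
    assert not strat["high_burden"].any()


def test_stratify_too_few_individuals_error():
    weeks = list(WEEKS)
    vals = {"CRP": {("P01", w): 20.0 for w in weeks}}
    agg = build_agg(vals, ["P01"], weeks)
    p = panels.PanelDefinition("x", ("CRP",))
    with pytest.raises(ValidationError):
        panels.stratify_burden(agg, p, p, p)
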