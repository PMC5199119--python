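"""Paired weight-loss screen: deltas, one-sample t, BH control, long-term calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_agg
from plasmaprofiler import differential
from plasmaprofiler.model import NotEvaluableError, ValidationError


def _two_week_agg(pairs: dict):
    """pairs: accession -> (value at -8, value at 0) as linear intensities."""
    vals = {
        acc: {("P01", -8): np.log2(a), ("P01", 0): np.log2(b)}
        for acc, (a, b) in pairs.items()
    }
    return build_agg(vals, ["P01"], [-8, 0])


def test_paired_delta_examples():
    agg = _two_week_agg(
        {"SAME": (100, 100), "UP37": (100, 137), "DOWN16": (100, 84)}
    )
    d = differential.paired_deltas(agg)
    assert d.loc["SAME", "P01"] == pytest.approx(0.0)
    assert d.loc["UP37", "P01"] == pytest.approx(0.4541759, rel=1e-6)
    assert d.loc["DOWN16", "P01"] == pytest.approx(-0.2515388, rel=1e-6)


def test_one_sample_test_matches_textbook_formula():
    """Frozen oracle: m=0.2, s=0.0816497, n=4 -> t=4.898979, p=0.016277 (t3)."""
    res = differential.one_sample_test([0.1, 0.2, 0.3, 0.2])
    assert res.t == pytest.approx(4.898979485566, rel=1e-9)
    assert res.p == pytest.approx(0.016276603459, rel=1e-9)


def test_one_sample_test_degenerate_inputs():
    assert differential.one_sample_test([0.0, 0.0, 0.0]) == (0.0, 1.0, 3)
    t, p, n = differential.one_sample_test([0.5, 0.5, 0.5])
    assert np.isinf(t) and t > 0 and p == 0.0
    with pytest.raises(NotEvaluableError):
        differential.one_sample_test([-1.0, 1.0])


def _bh_bruteforce(p, alpha=0.05):
    """Independent step-up oracle: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def test_bh_examples():
    q, rej = differential.bh_adjust([0.04])
    assert q[0] == pytest.approx(0.04) and rej[0]
    q, rej = differential.bh_adjust([0.01, 0.02, 0.03, 0.5])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])
    q, rej = differential.bh_adjust([1.0, 1.0, 1.0])
    assert not rej.any()
    with pytest.raises(ValidationError):
        differential.bh_adjust([0.5, 1.5])


@settings(max_examples=60, deadline=None)
@given(
    p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=60),
    alpha=st.sampled_from([0.01, 0.05, 0.1]),
)
def test_bh_agrees_with_bruteforce(p, alpha):
    q, rej = differential.bh_adjust(p, alpha=alpha)
    q2, rej2 = _bh_bruteforce(p, alpha=alpha)
    assert np.allclose(q, q2)
    assert (rej == rej2).all()


def test_screen_matches_scalar_test_per_protein():
    """The vectorized screen reproduces one_sample_test row by row."""
    rng = np.random.default_rng(8)
    inds = [f"P{i:02d}" for i in range(12)]
    vals = {}
    for k in range(15):
        base = rng.uniform(20, 24, 12)
        d = rng.normal(0.1, 0.2, 12)
        cells = {}
        for i, ind in enumerate(inds):
            if rng.random() < 0.15:
                continue  # leave some pairs missing
            cells[(ind, -8)] = base[i]
            cells[(ind, 0)] = base[i] + d[i]
        vals[f"A{k}"] = cells
    agg = build_agg(vals, inds, [-8, 0])
    screen = differential.differential_screen(agg)
    deltas = differential.paired_deltas(agg)
    for acc in screen.index:
        ref = differential.one_sample_test(deltas.loc[acc])
        assert screen.loc[acc, "t"] == pytest.approx(ref.t, rel=1e-10)
        assert screen.loc[acc, "p"] == pytest.approx(ref.p, rel=1e-10)
        assert screen.loc[acc, "n"] == ref.n


def test_screen_pairing_invariance():
    """Adding a per-individual constant to both weeks leaves the test unchanged."""
    rng = np.random.default_rng(4)
    inds = [f"P{i:02d}" for i in range(1, 11)]
    base = rng.uniform(20, 24, 10)
    deltas = rng.normal(0.3, 0.1, 10)
    vals = {
        "A": {
            **{(ind, -8): base[i] for i, ind in enumerate(inds)},
            **{(ind, 0): base[i] + deltas[i] for i, ind in enumerate(inds)},
        }
    }
    agg1 = build_agg(vals, inds, [-8, 0])
    shift = rng.uniform(-3, 3, 10)
    vals2 = {
        "A": {
            **{(ind, -8): base[i] + shift[i] for i, ind in enumerate(inds)},
            **{(ind, 0): base[i] + deltas[i] + shift[i] for i, ind in enumerate(inds)},
        }
    }
    agg2 = build_agg(vals2, inds, [-8, 0])
    s1 = differential.differential_screen(agg1)
    s2 = differential.differential_screen(agg2)
    assert s1.loc["A", "t"] == pytest.approx(s2.loc["A", "t"])
    assert s1.loc["A", "p"] == pytest.approx(s2.loc["A", "p"])


def test_median_percent_change_matches_definition():
    agg = _two_week_agg({"UP37": (100, 137)})
    agg.values[("P02", -8)] = np.log2(100)
    agg.values[("P02", 0)] = np.log2(137)
    agg.values[("P03", -8)] = np.log2(100)
    agg.values[("P03", 0)] = np.log2(137)
    screen = differential.differential_screen(agg)
    assert screen.loc["UP37", "median_percent_change"] == pytest.approx(37.0)


def _longterm_agg(step=0.6, flip=False, n_ind=20, seed=0):
    """One planted protein vs baseline across the six later weeks."""
    rng = np.random.default_rng(seed)
    weeks = [-8, 0, 4, 13, 26, 39, 52]
    inds = [f"P{i:02d}" for i in range(n_ind)]
    vals = {"X": {}, **{f"N{k}": {} for k in range(30)}}
    for i, ind in enumerate(inds):
        base = rng.uniform(20, 22)
        for w in weeks:
            eff = step if w > -8 else 0.0
            if flip and w in (4, 26, 39):
                eff = -step
            vals["X"][(ind, w)] = base + eff + rng.normal(0, 0.1)
            for k in range(30):
                vals[f"N{k}"][(ind, w)] = (
                    rng.uniform(20, 22) + rng.normal(0, 0.1)
                )
    return build_agg(vals, inds, weeks)


def test_long_term_step_and_hold_called_up():
    agg = _longterm_agg(step=0.6)
    out = differential.long_term_effects(agg)
    assert out.loc["X", "call"] == "up"


def test_long_term_alternating_sign_not_called():
    agg = _longterm_agg(step=0.6, flip=True)
    out = differential.long_term_effects(agg)
    assert out.loc["X", "call"] == "none"


def test_long_term_missing_week_is_error():
    agg = _two_week_agg({"A": (10, 12)})
    with pytest.raises(ValidationError):
        differential.long_term_effects(agg)


def test_planted_effects_recovered_with_fdr_control(default_cohort, default_agg):
    """Effects >= 1.2-fold recalled at >= 90% with observed FDP <= 10%."""
    from plasmaprofiler.simulate import ARCHETYPE_SHAPES, WEEKS

    truth = default_cohort.truth.proteins
    screen = differential.differential_screen(default_agg)
    merged = screen.join(truth[["archetype", "delta_log2"]])
    g0 = merged["archetype"].map(lambda a: ARCHETYPE_SHAPES[a][WEEKS.index(0)])
    week0_active = (merged["delta_log2"].abs() * g0) >= np.log2(1.2)
    planted = merged[(merged["archetype"] != "null") & week0_active]
    assert planted["significant"].mean() >= 0.90
    discoveries = merged[merged["significant"]]
    assert (discoveries["archetype"] == "null").mean() <= 0.10
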