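"""Weight-loss differential screen.

Because plasma protein levels are strongly individual-specific, the unit
of replication is the individual: for each protein we form the paired
per-individual log2 fold change between two weeks and test the deltas
against zero with a two-sided one-sample t-test, controlling the false
discovery rate across proteins with Benjamini-Hochberg.  Long-term calls
require a BH-significant same-direction change in at least five of the
six post-baseline comparisons.
"""

from __future__ import annotations

import logging
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AggregatedMatrix, NotEvaluableError, ValidationError

logger = logging.getLogger(__name__)

FDR_ALPHA = 0.05
HIGH_SIGNIFICANCE_P = 5e-4
MIN_N = 3

TTestResult = namedtuple("TTestResult", ["t", "p", "n"])


def paired_deltas(
    agg: AggregatedMatrix, week_from: int = -8, week_to: int = 0
) -> pd.DataFrame:
    """Per-individual paired log2 fold changes, proteins x individuals.

    Pairs with either side missing are dropped (NaN in the output).
    """
    for w in (week_from, week_to):
        if w not in agg.weeks:
            raise ValidationError(f"week {w} absent from aggregated matrix")
    a = agg.week_slice(week_from)
    b = agg.week_slice(week_to)
    common = [c for c in a.columns if c in set(b.columns)]
    deltas = b[common] - a[common]
    n_dropped = int((a[common].isna() ^ b[common].isna()).to_numpy().sum())
    if n_dropped:
        logger.info(
            "paired_deltas %s->%s: %d half-observed pair(s) dropped",
            week_from, week_to, n_dropped,
        )
    return deltas


def one_sample_test(deltas) -> TTestResult:
    """Two-sided one-sample t-test of mean delta = 0.

    Degenerate inputs: an all-zero vector gives (t=0, p=1); zero variance
    with a non-zero mean gives the p = 0 sentinel (with a warning).
    """
    arr = np.asarray(pd.Series(deltas).dropna(), dtype=float)
    n = len(arr)
    if n < MIN_N:
        raise NotEvaluableError(f"one-sample t-test needs n >= {MIN_N}, got {n}")
    if np.allclose(arr.std(ddof=1), 0.0):
        if np.allclose(arr.mean(), 0.0):
            return TTestResult(0.0, 1.0, n)
        logger.warning("zero-variance deltas with non-zero mean: p = 0 sentinel")
        return TTestResult(np.inf if arr.mean() > 0 else -np.inf, 0.0, n)
    t, p = stats.ttest_1samp(arr, 0.0)
    return TTestResult(float(t), float(p), n)


def bh_adjust(pvalues, alpha: float = FDR_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection set."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def differential_screen(
    agg: AggregatedMatrix,
    week_from: int = -8,
    week_to: int = 0,
    alpha: float = FDR_ALPHA,
    high_p: float = HIGH_SIGNIFICANCE_P,
) -> pd.DataFrame:
    """Per-protein paired screen between two weeks.

    Returns one row per testable protein with the t statistic, raw and
    BH-adjusted p, the mean log2 delta, and the median percent change
    (median over individuals of ``2**delta - 1``).
    """
    deltas = paired_deltas(agg, week_from, week_to)
    arr = deltas.to_numpy(dtype=float)
    n = np.isfinite(arr).sum(axis=1)
    keep = n >= MIN_N
    arr = arr[keep]
    n = n[keep]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=1)
        sd = np.nanstd(arr, axis=1, ddof=1)
        t = np.where(
            np.isclose(sd, 0.0),
            np.where(np.isclose(mean, 0.0), 0.0, np.sign(mean) * np.inf),
            mean / (sd / np.sqrt(n)),
        )
        p = np.where(
            np.isclose(sd, 0.0),
            np.where(np.isclose(mean, 0.0), 1.0, 0.0),
            2.0 * stats.t.sf(np.abs(t), n - 1),
        )
    if np.any(np.isclose(sd, 0.0) & ~np.isclose(mean, 0.0)):
        logger.warning("zero-variance deltas with non-zero mean: p = 0 sentinel")
    median_pct = np.nanmedian(100.0 * (np.power(2.0, arr) - 1.0), axis=1)
    idx = deltas.index[keep]
    out = pd.DataFrame(
        {
            "gene_symbol": agg.proteins.loc[idx, "gene_symbol"],
            "n": n,
            "mean_delta_log2": mean,
            "median_percent_change": median_pct,
            "t": t,
            "p": p,
        },
        index=idx.rename("accession"),
    )
    if len(out):
        q, reject = bh_adjust(out["p"].to_numpy(), alpha)
        out["q"] = q
        out["significant"] = reject
        out["highly_significant"] = out["p"] < high_p
    else:
        out["q"] = []
        out["significant"] = []
        out["highly_significant"] = []
    return out


def long_term_effects(
    agg: AggregatedMatrix,
    baseline: int = -8,
    weeks: tuple[int, ...] = (0, 4, 13, 26, 39, 52),
    alpha: float = FDR_ALPHA,
    min_weeks: int = 5,
) -> pd.DataFrame:
    """Proteins with a consistent significant change versus baseline.

    Runs the paired screen for every week against the baseline and calls a
    protein "up" ("down") when it is BH-significant with a positive
    (negative) mean delta in at least ``min_weeks`` of the comparisons.
    """
    missing = [w for w in (baseline, *weeks) if w not in agg.weeks]
    if missing:
        raise ValidationError(f"week(s) {missing} absent from aggregated matrix")
    up = pd.Series(0, index=agg.values.index)
    down = pd.Series(0, index=agg.values.index)
    min_p = pd.Series(1.0, index=agg.values.index)
    for w in weeks:
        screen = differential_screen(agg, baseline, w, alpha=alpha)
        sig = screen[screen["significant"]]
        up.loc[sig.index[sig["mean_delta_log2"] > 0]] += 1
        down.loc[sig.index[sig["mean_delta_log2"] < 0]] += 1
        min_p.loc[screen.index] = np.minimum(min_p.loc[screen.index], screen["p"])
    call = np.where(up >= min_weeks, "up", np.where(down >= min_weeks, "down", "none"))
    out = pd.DataFrame(
        {
            "gene_symbol": agg.proteins["gene_symbol"],
            "n_sig_up": up,
            "n_sig_down": down,
            "min_p": min_p,
            "call": call,
        }
    )
    return out


def highly_significant_proteins(
    agg: AggregatedMatrix,
    baseline: int = -8,
    weeks: tuple[int, ...] = (0, 4, 13, 26, 39, 52),
    high_p: float = HIGH_SIGNIFICANCE_P,
) -> list[str]:
    """Proteins changing highly significantly at >= 1 week versus baseline."""
    hits: set[str] = set()
    for w in weeks:
        if w not in agg.weeks:
            continue
        screen = differential_screen(agg, baseline, w)
        hits |= set(screen.index[screen["p"] < high_p])
    return sorted(hits)
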