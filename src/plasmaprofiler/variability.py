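"""Individual-specificity of plasma protein levels.

Protein levels vary widely between people yet stay remarkably constant
within a person over a year.  This module quantifies that with, per
(protein, individual):

* the longitudinal coefficient of variation (CV = sample sd / mean of the
  linear-scale aggregated intensities over the five maintenance weeks),
* the log2 fold difference of the individual's mean level versus the
  cohort mean (the individual remains part of the cohort average),

and classifies records as individual-specific at a 2x or 5x fold cutoff
with CV <= 30%, or as tightly controlled (protein-level rule: fold
difference < 1.3 and CV < 20% for every individual).  The weight-loss
weeks (-8, 0) are excluded so the statistics reflect steady-state
variability, not the intervention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    MAINTENANCE_WEEKS,
    AggregatedMatrix,
    NotEvaluableError,
    ValidationError,
)

CV_CUTOFF = 0.30
FOLD_CUTOFF_2X = 1.0          # log2 units
FOLD_CUTOFF_5X = float(np.log2(5))
TIGHT_FOLD_CUTOFF = float(np.log2(1.3))
TIGHT_CV_CUTOFF = 0.20


def longitudinal_cv(values) -> float:
    """Sample sd / mean of the five maintenance-week linear intensities."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) != len(MAINTENANCE_WEEKS):
        raise ValidationError(
            f"longitudinal CV expects {len(MAINTENANCE_WEEKS)} values"
        )
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise NotEvaluableError("CV needs all five maintenance weeks observed and > 0")
    return float(arr.std(ddof=1) / arr.mean())


def fold_difference(individual_mean: float, cohort_mean: float) -> float:
    """log2 of an individual's mean level over the cohort mean level."""
    if individual_mean <= 0 or cohort_mean <= 0:
        raise ValidationError("fold difference needs positive linear means")
    return float(np.log2(individual_mean / cohort_mean))


def classify(
    cv: float,
    log2_fold_diff: float,
    cut_fold_2: float = FOLD_CUTOFF_2X,
    cut_fold_5: float = FOLD_CUTOFF_5X,
    cut_cv: float = CV_CUTOFF,
) -> str:
    """Record-level class: ``specific_5x`` implies ``specific_2x``."""
    fold = abs(log2_fold_diff)
    if fold >= cut_fold_5 and cv <= cut_cv:
        return "specific_5x"
    if fold >= cut_fold_2 and cv <= cut_cv:
        return "specific_2x"
    return "none"


def variability_records(
    agg: AggregatedMatrix, weeks: tuple[int, ...] = MAINTENANCE_WEEKS
) -> pd.DataFrame:
    """CV / fold-difference records for every (protein, individual).

    A record exists only where the protein is observed at all maintenance
    weeks for that individual (the CV is undefined otherwise).  The cohort
    mean for the fold difference averages the per-individual means of all
    individuals with a complete record, including the one under test.
    """
    linear = agg.linear()
    cols = [c for c in linear.columns if c[1] in weeks]
    sub = linear[cols]
    rows = []
    for acc in sub.index:
        wide = sub.loc[acc].unstack(level="week")
        complete = wide.dropna()
        complete = complete[(complete > 0).all(axis=1)]
        if complete.empty:
            continue
        means = complete.mean(axis=1)
        cohort_mean = float(means.mean())
        for ind, row in complete.iterrows():
            cv = float(row.std(ddof=1) / row.mean())
            fold = fold_difference(float(means[ind]), cohort_mean)
            rows.append(
                {
                    "accession": acc,
                    "gene_symbol": agg.proteins.loc[acc, "gene_symbol"],
                    "individual_id": ind,
                    "cv_longitudinal": cv,
                    "log2_fold_diff": fold,
                    "class": classify(cv, fold),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "gene_symbol", "individual_id",
            "cv_longitudinal", "log2_fold_diff", "class",
        ],
    )


def tightly_controlled_proteins(
    records: pd.DataFrame,
    tight_fold: float = TIGHT_FOLD_CUTOFF,
    tight_cv: float = TIGHT_CV_CUTOFF,
    min_individuals: int = 3,
) -> list[str]:
    """Proteins whose level varies little between and within all individuals.

    Protein-level rule: max |log2 fold difference| over individuals below
    ``tight_fold`` AND max CV below ``tight_cv``, assessed only for
    proteins with records in at least ``min_individuals`` individuals.
    """
    if records.empty:
        return []
    out = []
    for acc, grp in records.groupby("accession"):
        if len(grp) < min_individuals:
            continue
        if (
            grp["log2_fold_diff"].abs().max() < tight_fold
            and grp["cv_longitudinal"].max() < tight_cv
        ):
            out.append(acc)
    return out


def cohort_specificity_summary(records: pd.DataFrame) -> dict[str, float]:
    """Cohort-level individual-specificity fractions over protein maxima.

    For each protein, the maximum |log2 fold difference| over individuals
    determines whether it exceeds the 2x / 5x cutoffs anywhere in the
    cohort; a protein counts as individual-specific at (2x, 30% CV) when
    at least one individual passes both gates.
    """
    if records.empty:
        raise ValidationError("no variability records")
    frac2 = frac5 = frac_spec = 0
    n = 0
    for _, grp in records.groupby("accession"):
        n += 1
        fold_max = grp["log2_fold_diff"].abs().max()
        frac2 += fold_max >= FOLD_CUTOFF_2X
        frac5 += fold_max >= FOLD_CUTOFF_5X
        frac_spec += (
            (grp["log2_fold_diff"].abs() >= FOLD_CUTOFF_2X)
            & (grp["cv_longitudinal"] <= CV_CUTOFF)
        ).any()
    return {
        "fraction_over_2x": frac2 / n,
        "fraction_over_5x": frac5 / n,
        "fraction_specific_2x_cv30": frac_spec / n,
        "n_proteins": n,
    }
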