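"""Matrix cleaning, replicate aggregation and completeness filters."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import (
    MAINTENANCE_WEEKS,
    AggregatedMatrix,
    IntensityMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def remove_flagged_proteins(matrix: IntensityMatrix) -> IntensityMatrix:
    """Drop reverse-database hits and contaminants (e.g. keratins)."""
    flags = matrix.proteins["is_contaminant"] | matrix.proteins["is_reverse"]
    n_removed = int(flags.sum())
    if n_removed:
        logger.info(
            "removed %d flagged protein group(s): %d contaminant, %d reverse",
            n_removed,
            int(matrix.proteins["is_contaminant"].sum()),
            int(matrix.proteins["is_reverse"].sum()),
        )
    keep = list(matrix.proteins.index[~flags])
    return matrix.subset_proteins(keep)


def aggregate_replicates(
    matrix: IntensityMatrix, method: str = "median"
) -> AggregatedMatrix:
    """Collapse technical replicates to one log2 value per (individual, week).

    The default aggregator is the median of the observed log2 replicate
    intensities (robust to a single outlying replicate); the mean is
    available for sensitivity analysis.  A cell is missing only when all
    replicates are missing, and the number of observed replicates behind
    each cell is recorded.
    """
    if method not in ("median", "mean"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    log2v = matrix.log2()
    key = pd.MultiIndex.from_frame(
        matrix.samples[["individual_id", "week"]].reset_index(drop=True)
    )
    grouped = log2v.T.set_axis(key).groupby(level=[0, 1])
    agg = (grouped.median() if method == "median" else grouped.mean()).T
    counts = log2v.notna().T.set_axis(key).groupby(level=[0, 1]).sum().T.astype(int)
    agg.columns = agg.columns.set_names(["individual_id", "week"])
    counts.columns = counts.columns.set_names(["individual_id", "week"])
    return AggregatedMatrix(
        values=agg, counts=counts, proteins=matrix.proteins.copy(), method=method
    )


def filter_maintenance_complete(
    agg: AggregatedMatrix, weeks: tuple[int, ...] = MAINTENANCE_WEEKS
) -> list[str]:
    """Proteins quantified at every maintenance week in at least one individual."""
    present_weeks = set(agg.weeks)
    missing = [w for w in weeks if w not in present_weeks]
    if missing:
        raise ValidationError(f"maintenance week(s) {missing} absent from matrix")
    observed = agg.values.notna()
    keep: list[str] = []
    for acc in agg.values.index:
        row = observed.loc[acc]
        by_ind = row.groupby(level="individual_id")
        for _, sub in by_ind:
            got = set(sub[sub].index.get_level_values("week"))
            if set(weeks) <= got:
                keep.append(acc)
                break
    return keep
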