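"""Plasma sample quality control.

Shotgun plasma proteomics carries its own QC readouts: erythrocyte lysis
shows up as elevated levels of the highly abundant erythrocyte-specific
proteins (HBA1, HBB, HBD, CA1), and (partial) blood coagulation during
sampling as depleted fibrinogen chains (FGA, FGB, FGG).  Both are scored
as the mean log2 deviation of the marker proteins from the cohort median;
replicate reproducibility is summarized as the mean pairwise Pearson
correlation within each quadruplicate.

Flags annotate runs; they never auto-exclude them (exclusion is a pipeline
configuration switch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .model import AnnotationTable, IntensityMatrix, NotEvaluableError

logger = logging.getLogger(__name__)

LYSIS_THRESHOLD_LOG2 = 3.0
COAGULATION_THRESHOLD_LOG2 = -2.0
MIN_SHARED_PROTEINS = 10


@dataclass
class QCReport:
    """Per-run QC scores/flags and per-quadruplicate reproducibility."""

    run_scores: pd.DataFrame        # lysis/coagulation score + flag per run
    replicate_groups: pd.DataFrame  # mean pairwise r per (individual, week)
    cohort_mean_r: float

    @property
    def lysis_flagged(self) -> list[str]:
        return list(self.run_scores.index[self.run_scores["lysis_flag"]])

    @property
    def coagulation_flagged(self) -> list[str]:
        return list(self.run_scores.index[self.run_scores["coagulation_flag"]])


def _marker_deviation_score(
    matrix: IntensityMatrix, marker_genes: list[str], what: str
) -> pd.Series:
    accs = matrix.accessions_for(marker_genes)
    genes_present = {matrix.proteins.loc[a, "gene_symbol"] for a in accs}
    if len(genes_present) < 2:
        raise NotEvaluableError(
            f"{what} QC needs >= 2 marker proteins, found {sorted(genes_present)}"
        )
    log2v = matrix.log2().loc[accs]
    cohort_median = log2v.median(axis=1)
    deviation = log2v.sub(cohort_median, axis=0)
    return deviation.mean(axis=0, skipna=True)


def score_lysis(
    matrix: IntensityMatrix,
    annotations: AnnotationTable,
    threshold_log2: float = LYSIS_THRESHOLD_LOG2,
) -> pd.DataFrame:
    """Score erythrocyte lysis per run.

    The score is the mean, over observed erythrocyte markers, of the run's
    log2 intensity minus the cohort median log2 intensity of that marker;
    a run is flagged when the score exceeds ``threshold_log2``.
    """
    markers = annotations.genes_with_flag("erythrocyte_marker")
    score = _marker_deviation_score(matrix, markers, "lysis")
    return pd.DataFrame(
        {"lysis_score": score, "lysis_flag": score > threshold_log2}
    )


def score_coagulation(
    matrix: IntensityMatrix,
    annotations: AnnotationTable,
    threshold_log2: float = COAGULATION_THRESHOLD_LOG2,
) -> pd.DataFrame:
    """Score blood coagulation per run (depleted fibrinogens flag below threshold)."""
    fibs = annotations.genes_with_flag("fibrinogen")
    score = _marker_deviation_score(matrix, fibs, "coagulation")
    return pd.DataFrame(
        {"coagulation_score": score, "coagulation_flag": score < threshold_log2}
    )


def replicate_reproducibility(
    matrix: IntensityMatrix, min_shared: int = MIN_SHARED_PROTEINS
) -> tuple[pd.DataFrame, float]:
    """Mean pairwise Pearson r within each technical replicate group.

    Correlations use pairwise-complete log2 intensities; pairs sharing
    fewer than ``min_shared`` proteins are skipped (and logged).  Returns
    the per-(individual, week) table and the cohort mean over groups.
    """
    log2v = matrix.log2()
    arr = log2v.to_numpy()
    col_of = {run: k for k, run in enumerate(log2v.columns)}
    rows = []
    for (ind, week), grp in matrix.samples.groupby(["individual_id", "week"]):
        runs = list(grp.index)
        rs = []
        skipped = 0
        for a, b in combinations(runs, 2):
            va, vb = arr[:, col_of[a]], arr[:, col_of[b]]
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < min_shared:
                skipped += 1
                continue
            xa, xb = va[ok], vb[ok]
            if xa.std() == 0 or xb.std() == 0:
                skipped += 1
                continue
            rs.append(float(np.corrcoef(xa, xb)[0, 1]))
        if skipped:
            logger.info(
                "replicate group (%s, week %s): skipped %d pair(s) with < %d "
                "shared proteins", ind, week, skipped, min_shared,
            )
        rows.append(
            {
                "individual_id": ind,
                "week": week,
                "n_replicates": len(runs),
                "n_pairs_used": len(rs),
                "mean_pairwise_r": float(np.mean(rs)) if rs else np.nan,
            }
        )
    groups = pd.DataFrame(rows).set_index(["individual_id", "week"])
    cohort_mean = float(groups["mean_pairwise_r"].mean())
    return groups, cohort_mean


def qc_report(
    matrix: IntensityMatrix,
    annotations: AnnotationTable,
    lysis_threshold_log2: float = LYSIS_THRESHOLD_LOG2,
    coagulation_threshold_log2: float = COAGULATION_THRESHOLD_LOG2,
    min_shared: int = MIN_SHARED_PROTEINS,
) -> QCReport:
    """Full QC report: lysis, coagulation and replicate reproducibility."""
    lysis = score_lysis(matrix, annotations, lysis_threshold_log2)
    coag = score_coagulation(matrix, annotations, coagulation_threshold_log2)
    groups, cohort_mean = replicate_reproducibility(matrix, min_shared)
    return QCReport(
        run_scores=lysis.join(coag),
        replicate_groups=groups,
        cohort_mean_r=cohort_mean,
    )
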