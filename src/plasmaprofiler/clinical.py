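"""Correlation of protein levels with clinical laboratory parameters.

Observations pool individuals and weeks: each (individual, week) pair
where both the aggregated protein level (log2) and the clinical variable
are observed contributes one point.  Pearson's r with its two-sided
t-transform p-value is computed per protein and Benjamini-Hochberg
adjusted across proteins within each clinical variable.  No
within-individual de-correlation adjustment is applied — repeated
measures from one person count as separate observations, matching how
longitudinal biomarker correlations are conventionally screened.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .model import AggregatedMatrix, ClinicalTable, NotEvaluableError, ValidationError

logger = logging.getLogger(__name__)

MIN_N = 10
FDR_ALPHA = 0.05


def paired_observations(
    agg: AggregatedMatrix,
    clinical: ClinicalTable,
    variable: str,
    accession: str,
    min_n: int = MIN_N,
) -> pd.DataFrame:
    """Aligned (protein log2, clinical value) vectors over (individual, week)."""
    clin = clinical.series(variable)
    prot = agg.values.loc[accession].dropna()
    common = prot.index.intersection(clin.index)
    if len(common) < min_n:
        raise NotEvaluableError(
            f"{accession} x {variable}: only {len(common)} paired observations"
        )
    return pd.DataFrame(
        {"protein_log2": prot.loc[common], "clinical": clin.loc[common]}
    )


def correlate_all(
    agg: AggregatedMatrix,
    clinical: ClinicalTable,
    variable: str,
    min_n: int = MIN_N,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Pearson correlation of every protein with one clinical variable.

    Proteins with fewer than ``min_n`` paired observations or zero
    variance are recorded as not evaluable (NaN r, excluded from the BH
    adjustment).
    """
    clin = clinical.series(variable)
    rows = []
    for acc in agg.values.index:
        prot = agg.values.loc[acc].dropna()
        common = prot.index.intersection(clin.index)
        rec = {
            "accession": acc,
            "gene_symbol": agg.proteins.loc[acc, "gene_symbol"],
            "variable": variable,
            "n": len(common),
            "r": np.nan,
            "p": np.nan,
        }
        if len(common) >= min_n:
            x = prot.loc[common].to_numpy()
            y = clin.loc[common].to_numpy()
            if x.std() > 0 and y.std() > 0:
                r, p = stats.pearsonr(x, y)
                rec["r"], rec["p"] = float(r), float(p)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("accession")
    evaluable = out["p"].notna()
    out["q"] = np.nan
    out["significant"] = False
    if evaluable.any():
        q, reject = bh_adjust(out.loc[evaluable, "p"].to_numpy(), alpha)
        out.loc[evaluable, "q"] = q
        out.loc[evaluable, "significant"] = reject
    n_skip = int((~evaluable).sum())
    if n_skip:
        logger.info("%s: %d protein(s) not evaluable", variable, n_skip)
    return out


def correlate_variables(
    agg: AggregatedMatrix,
    clinical: ClinicalTable,
    variables: list[str] | None = None,
    min_n: int = MIN_N,
    alpha: float = FDR_ALPHA,
) -> dict[str, pd.DataFrame]:
    """Run :func:`correlate_all` for each clinical variable."""
    variables = variables or clinical.variables
    return {
        v: correlate_all(agg, clinical, v, min_n=min_n, alpha=alpha)
        for v in variables
    }
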