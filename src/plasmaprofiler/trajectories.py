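"""Longitudinal trajectory profiles and archetype clustering.

Cohort-median log2 profiles of the highly significantly changing proteins
are Z-scored over the seven time points (population-sd convention, the
usual heat-map normalization) and grouped by agglomerative hierarchical
clustering (Euclidean distance, average linkage) into longitudinal
archetypes.  Percent-of-baseline profiles normalize each individual's
trajectory to its own pre-weight-loss level (week -8 = 100%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .model import (
    WEEKS,
    AggregatedMatrix,
    NotEvaluableError,
    ValidationError,
)

N_CLUSTERS = 7


def zscore_over_time(profile) -> np.ndarray:
    """Z-score a time profile with the population-sd (divide by n) convention.

    Missing weeks stay missing; a constant profile maps to all zeros; fewer
    than two observed weeks is not evaluable.
    """
    arr = np.asarray(profile, dtype=float)
    ok = np.isfinite(arr)
    if ok.sum() < 2:
        raise NotEvaluableError("z-scoring needs >= 2 observed weeks")
    out = np.full_like(arr, np.nan)
    obs = arr[ok]
    sd = obs.std()  # population convention (ddof = 0)
    out[ok] = 0.0 if sd == 0 else (obs - obs.mean()) / sd
    return out


def median_profiles(
    agg: AggregatedMatrix, accessions: list[str] | None = None
) -> pd.DataFrame:
    """Cohort-median log2 intensity per week (proteins x weeks).

    The median per week is taken over aggregated (individual, week) values,
    not over raw runs.
    """
    values = agg.values if accessions is None else agg.values.loc[accessions]
    return values.T.groupby(level="week").median().T


def zscored_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scored time profiles (drops rows with < 2 observed weeks)."""
    rows = {}
    for acc in profiles.index:
        try:
            rows[acc] = zscore_over_time(profiles.loc[acc].to_numpy())
        except NotEvaluableError:
            continue
    return pd.DataFrame.from_dict(rows, orient="index", columns=profiles.columns)


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = N_CLUSTERS,
    distance: str = "euclidean",
    method: str = "average",
) -> pd.Series:
    """Cut an agglomerative tree over complete z-profiles into ``k`` clusters.

    Rows are sorted by index before linkage, which makes the result
    independent of input order; ties resolve to the lowest-index merge.
    """
    if profiles.isna().any().any():
        raise ValidationError("clustering needs complete z-score vectors")
    if len(profiles) < k:
        raise ValidationError(f"need >= {k} profiles to form {k} clusters")
    ordered = profiles.sort_index()
    z = linkage(ordered.to_numpy(), method=method, metric=distance)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=ordered.index, name="cluster_id").reindex(
        profiles.index
    )


def trajectory_table(
    agg: AggregatedMatrix, accessions: list[str], k: int = N_CLUSTERS
) -> pd.DataFrame:
    """Median profile + z-profile + cluster id per selected protein."""
    med = median_profiles(agg, accessions)
    z = zscored_profiles(med)
    complete = z.dropna()
    labels = cluster_profiles(complete, k=min(k, len(complete)))
    out = pd.concat(
        [med.add_prefix("median_log2_w"), z.add_prefix("z_w")], axis=1
    )
    out["cluster_id"] = labels.reindex(out.index)
    out.insert(0, "gene_symbol", agg.proteins.loc[out.index, "gene_symbol"])
    return out


def percent_of_baseline(
    agg: AggregatedMatrix, accession: str, baseline_week: int = -8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual percent-of-baseline profile and its cohort summary.

    Each individual's linear intensities are scaled so the baseline week
    equals 100%; individuals lacking the baseline are skipped.  Returns
    (individuals x weeks percent table, per-week mean +/- SEM summary).
    """
    if accession not in agg.values.index:
        raise ValidationError(f"unknown protein {accession!r}")
    wide = agg.values.loc[accession].unstack(level="week")
    if baseline_week not in wide.columns:
        raise ValidationError(f"baseline week {baseline_week} absent")
    base = wide[baseline_week]
    kept = wide[base.notna()]
    pct = 100.0 * np.power(2.0, kept.sub(kept[baseline_week], axis=0))
    n = pct.notna().sum()
    mean = pct.mean()
    sem = pct.std(ddof=1) / np.sqrt(n.where(n > 0))
    summary = pd.DataFrame({"mean_percent": mean, "sem": sem, "n": n})
    return pct, summary
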