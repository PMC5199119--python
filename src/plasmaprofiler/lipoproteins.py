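"""Lipoprotein-particle and lipid-process level aggregation.

Apolipoprotein trajectories are aggregated to the five main lipoprotein
particles (chylomicron, HDL, IDL, LDL, vLDL) via GOCC particle terms, and
to lipid-related biological processes via case-insensitive keyword
matching on GOBP term names (lipid, lipoprotein, fat, cholesterol).
Aggregation is a plain mean of the member z-profiles — no enrichment
statistic is attached.  The APOB/APOA1 ratio, a cardiovascular risk
indicator, is computed per individual on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AggregatedMatrix, AnnotationTable, NotEvaluableError, ValidationError
from .reference import PARTICLE_TERMS

logger = logging.getLogger(__name__)

GOBP_KEYWORDS: tuple[str, ...] = ("lipid", "lipoprotein", "fat", "cholesterol")


@dataclass
class AggregateProfile:
    """Mean z-profile of the member proteins of one GO term."""

    term: str
    members: tuple[str, ...]
    profile: pd.Series  # per-week mean z

    @property
    def member_count(self) -> int:
        return len(self.members)


def _mean_profile(z_profiles: pd.DataFrame, genes: list[str]) -> pd.Series:
    return z_profiles.loc[genes].mean(axis=0)


def particle_profiles(
    z_profiles: pd.DataFrame,
    annotations: AnnotationTable,
    particles: tuple[str, ...] = tuple(PARTICLE_TERMS),
) -> list[AggregateProfile]:
    """Per-particle mean z-profile over the member apolipoproteins.

    ``z_profiles`` is indexed by gene symbol (weeks as columns).  A
    requested particle without any measured member is dropped with a
    warning.
    """
    out = []
    for particle in particles:
        term = PARTICLE_TERMS.get(particle, particle)
        genes = [
            g
            for g in annotations.genes_with_term("gocc", term)
            if g in z_profiles.index
        ]
        if not genes:
            logger.warning("particle %r has no measured members; dropped", particle)
            continue
        out.append(
            AggregateProfile(
                term=particle,
                members=tuple(sorted(genes)),
                profile=_mean_profile(z_profiles, sorted(genes)),
            )
        )
    return out


def gobp_keyword_profiles(
    z_profiles: pd.DataFrame,
    annotations: AnnotationTable,
    keywords: tuple[str, ...] = GOBP_KEYWORDS,
) -> list[AggregateProfile]:
    """One aggregate per GOBP term whose name contains a lipid keyword."""
    wanted = [k.lower() for k in keywords]
    matched = sorted(
        term
        for term in annotations.terms("gobp")
        if any(k in term.lower() for k in wanted)
    )
    out = []
    for term in matched:
        genes = [
            g
            for g in annotations.genes_with_term("gobp", term)
            if g in z_profiles.index
        ]
        if genes:
            out.append(
                AggregateProfile(
                    term=term,
                    members=tuple(sorted(genes)),
                    profile=_mean_profile(z_profiles, sorted(genes)),
                )
            )
    if not out:
        logger.warning("no GOBP terms matched keywords %s", list(keywords))
    return out


def apob_apoa1_ratio(
    agg: AggregatedMatrix, individual_id: str, baseline_week: int = -8
) -> pd.DataFrame:
    """Per-week APOB/APOA1 linear intensity ratio for one individual.

    Returns the ratio and its percent change versus the baseline week
    (``100 * (ratio_t / ratio_baseline - 1)``); weeks where either protein
    is missing are skipped.
    """
    accs_b = agg.accessions_for(["APOB"])
    accs_a = agg.accessions_for(["APOA1"])
    if not accs_b or not accs_a:
        raise NotEvaluableError("APOB and APOA1 must both be present")
    if individual_id not in agg.individuals:
        raise ValidationError(f"unknown individual {individual_id!r}")
    series = agg.individual_slice(individual_id)
    apob = np.power(2.0, series.loc[accs_b].mean(axis=0))
    apoa1 = np.power(2.0, series.loc[accs_a].mean(axis=0))
    ratio = (apob / apoa1).dropna()
    if baseline_week not in ratio.index:
        raise NotEvaluableError(
            f"baseline week {baseline_week} missing for {individual_id}"
        )
    pct = 100.0 * (ratio / ratio[baseline_week] - 1.0)
    return pd.DataFrame({"ratio": ratio, "percent_change": pct})


def cohort_apob_apoa1(
    agg: AggregatedMatrix, baseline_week: int = -8
) -> pd.DataFrame:
    """Cohort summary of the per-individual ratio percent change.

    Reports mean +/- SEM per week together with the median: ratios of
    log-normal intensities are right-skewed, so the median is the robust
    location for "the cohort's ratio changed by x%".
    """
    per_ind = {}
    for ind in agg.individuals:
        try:
            per_ind[ind] = apob_apoa1_ratio(agg, ind, baseline_week)["percent_change"]
        except NotEvaluableError:
            continue
    if not per_ind:
        raise NotEvaluableError("no individual with a complete APOB/APOA1 baseline")
    wide = pd.DataFrame(per_ind).T
    n = wide.notna().sum()
    return pd.DataFrame(
        {
            "mean_percent_change": wide.mean(),
            "median_percent_change": wide.median(),
            "sem": wide.std(ddof=1) / np.sqrt(n.where(n > 0)),
            "n": n,
        }
    )
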