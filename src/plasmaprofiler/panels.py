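"""Biomarker panel construction and per-individual panel scoring.

Three panels are built from the screen results:

* the inflammation set — highly significantly changing proteins carrying
  the keywords "acute phase", "inflammatory response" or "immunity"
  (C1QA/B/C collapsed to one entry), minus the anti-inflammatory CD14,
  plus the non-annotated acute-phase proteins APCS and LBP;
* the ten-protein BMI panel — inflammation-set members with a
  BH-significant positive BMI correlation, ordered by p;
* the pro- / anti-insulin-resistance panels — the most significantly
  positively / negatively HOMA-IR-correlated proteins (immunoglobulin
  chains excluded).

Per-individual panel profiles z-score each member over the individual's
own time series, average members per week, and summarize the trajectory
with an ordinary-least-squares slope over actual week numbers; a negative
slope marks an individual whose inflammation profile benefited from
weight loss.  The metabolic-burden stratification intersects the high-IR
and high-inflammation sub-groups obtained from deterministic two-group
agglomerative splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .model import (
    AggregatedMatrix,
    AnnotationTable,
    NotEvaluableError,
    ValidationError,
)
from .reference import C1Q_CHAINS, INFLAMMATION_KEYWORDS

logger = logging.getLogger(__name__)

C1Q_ENTRY = "C1Q"
MIN_PANEL_WEEKS = 3


class EmptyPanelError(ValidationError):
    """Panel selection produced no members."""


@dataclass(frozen=True)
class PanelDefinition:
    """A named protein panel with per-member orientation and a filter trail."""

    name: str
    members: tuple[str, ...]
    orientation: tuple[tuple[str, int], ...] = ()
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.members:
            raise EmptyPanelError(f"panel {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"panel {self.name!r} has duplicate members")

    def orientation_of(self, member: str) -> int:
        return dict(self.orientation).get(member, 1)


@dataclass
class PanelScoreSeries:
    """One individual's longitudinal panel profile."""

    individual_id: str
    weekly_mean_z: pd.Series
    slope: float
    benefit: bool
    n_members_used: int


def build_inflammation_set(
    highly_significant: set[str] | list[str],
    annotations: AnnotationTable,
    keywords: tuple[str, ...] = INFLAMMATION_KEYWORDS,
    remove: tuple[str, ...] = ("CD14",),
    add: tuple[str, ...] = ("APCS", "LBP"),
    matrix_genes: set[str] | None = None,
) -> PanelDefinition:
    """Keyword-filter the highly significant proteins into the inflammation set.

    C1QA/B/C collapse to a single ``C1Q`` entry.  ``remove`` entries are
    dropped, ``add`` entries appended; an added protein absent from the
    measured matrix is kept in the definition with a warning.
    """
    hs = set(highly_significant)
    keyword_hits = set(annotations.genes_with_any_keyword(keywords)) & hs
    provenance = [f"keyword filter {sorted(keywords)}: {len(keyword_hits)} gene(s)"]
    if keyword_hits & set(C1Q_CHAINS):
        keyword_hits -= set(C1Q_CHAINS)
        keyword_hits.add(C1Q_ENTRY)
        provenance.append("collapsed C1QA/B/C to one entry")
    provenance.append(
        f"{len(keyword_hits)} keyword-annotated members (C1Q counted once)"
    )
    members = keyword_hits - set(remove)
    if keyword_hits & set(remove):
        provenance.append(f"removed {sorted(keyword_hits & set(remove))}")
    for gene in add:
        if matrix_genes is not None and gene not in matrix_genes:
            logger.warning("added panel protein %s not present in the matrix", gene)
        members.add(gene)
    provenance.append(f"added {sorted(add)}")
    return PanelDefinition(
        name="inflammation",
        members=tuple(sorted(members)),
        orientation=tuple((m, 1) for m in sorted(members)),
        provenance=tuple(provenance),
    )


def protein_slope(weeks, values) -> float:
    """Ordinary-least-squares slope of value against actual week number."""
    x = np.asarray(weeks, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise NotEvaluableError("slope needs >= 3 (week, value) points")
    return float(np.polyfit(x[ok], y[ok], 1)[0])


def _member_accessions(agg: AggregatedMatrix, member: str) -> list[str]:
    genes = list(C1Q_CHAINS) if member == C1Q_ENTRY else [member]
    return agg.accessions_for(genes)


def _zscore_series(s: pd.Series) -> pd.Series:
    obs = s.dropna()
    sd = obs.std(ddof=0)
    if sd == 0:
        return pd.Series(0.0, index=obs.index).reindex(s.index)
    return ((s - obs.mean()) / sd).where(s.notna())


def cohort_panel_slopes(agg: AggregatedMatrix, panel: PanelDefinition) -> pd.DataFrame:
    """Slope of each member's z-scored cohort-median profile over time."""
    rows = []
    for member in panel.members:
        accs = _member_accessions(agg, member)
        if not accs:
            continue
        med = agg.values.loc[accs].T.groupby(level="week").median().T.mean(axis=0)
        z = _zscore_series(med)
        try:
            slope = protein_slope(z.index.to_numpy(), z.to_numpy())
        except NotEvaluableError:
            continue
        rows.append({"member": member, "slope": slope, "negative": slope < 0})
    return pd.DataFrame(rows, columns=["member", "slope", "negative"]).set_index(
        "member"
    )


def select_bmi_panel(
    panel: PanelDefinition,
    bmi_correlations: pd.DataFrame,
    name: str = "bmi_ten_protein",
) -> PanelDefinition:
    """Inflammation-set members with a significant positive BMI correlation.

    ``bmi_correlations`` needs columns ``gene_symbol``, ``r``, ``p`` and
    ``significant``.  Members are ordered by ascending p (ties by |r|
    descending, then symbol); an empty selection raises
    :class:`EmptyPanelError`.
    """
    corr = bmi_correlations.reset_index()
    corr = corr[corr["significant"] & (corr["r"] > 0)]
    best: dict[str, tuple[float, float]] = {}
    for _, row in corr.iterrows():
        gene = row["gene_symbol"]
        member = C1Q_ENTRY if gene in C1Q_CHAINS else gene
        if member not in panel.members:
            continue
        p, r = float(row["p"]), float(row["r"])
        if member not in best or p < best[member][0]:
            best[member] = (p, r)
    if not best:
        raise EmptyPanelError("no panel member significantly correlates with BMI")
    ordered = sorted(best.items(), key=lambda kv: (kv[1][0], -abs(kv[1][1]), kv[0]))
    members = tuple(m for m, _ in ordered)
    return PanelDefinition(
        name=name,
        members=members,
        orientation=tuple((m, 1) for m in members),
        provenance=panel.provenance
        + (f"kept {len(members)} member(s) with significant positive BMI correlation",),
    )


def individual_panel_profile(
    agg: AggregatedMatrix,
    panel: PanelDefinition,
    individual_id: str,
    min_weeks: int = MIN_PANEL_WEEKS,
) -> PanelScoreSeries:
    """Panel z-profile, slope and benefit flag for one individual.

    Each member is z-scored over the individual's own time series
    (population sd); members observed in fewer than ``min_weeks`` weeks
    drop out of this individual's profile (logged).  The per-week panel
    value is the mean member z; the slope is OLS against week number and
    ``benefit`` means a negative slope.
    """
    if individual_id not in agg.individuals:
        raise ValidationError(f"unknown individual {individual_id!r}")
    series = agg.individual_slice(individual_id)
    member_z = {}
    for member in panel.members:
        accs = _member_accessions(agg, member)
        if not accs:
            continue
        chain_z = []
        for acc in accs:
            s = series.loc[acc]
            if s.notna().sum() < min_weeks:
                continue
            chain_z.append(_zscore_series(s) * panel.orientation_of(member))
        if chain_z:
            member_z[member] = pd.concat(chain_z, axis=1).mean(axis=1)
    dropped = len(panel.members) - len(member_z)
    if dropped:
        logger.info(
            "individual %s: %d panel member(s) dropped (< %d observed weeks)",
            individual_id, dropped, min_weeks,
        )
    if not member_z:
        raise NotEvaluableError(f"no panel member evaluable for {individual_id}")
    weekly = pd.DataFrame(member_z).mean(axis=1)
    slope = protein_slope(weekly.index.to_numpy(), weekly.to_numpy())
    return PanelScoreSeries(
        individual_id=individual_id,
        weekly_mean_z=weekly,
        slope=slope,
        benefit=slope < 0,
        n_members_used=len(member_z),
    )


def benefit_table(
    agg: AggregatedMatrix, panel: PanelDefinition, min_weeks: int = MIN_PANEL_WEEKS
) -> pd.DataFrame:
    """Panel slope and benefit flag per evaluable individual."""
    rows = []
    for ind in agg.individuals:
        try:
            prof = individual_panel_profile(agg, panel, ind, min_weeks)
        except (NotEvaluableError, ValidationError):
            continue
        rows.append(
            {
                "individual_id": ind,
                "slope": prof.slope,
                "benefit": prof.benefit,
                "n_members_used": prof.n_members_used,
            }
        )
    return pd.DataFrame(
        rows, columns=["individual_id", "slope", "benefit", "n_members_used"]
    ).set_index("individual_id")


def build_ir_panels(
    homa_correlations: pd.DataFrame,
    annotations: AnnotationTable,
    k_pos: int = 4,
    k_neg: int = 5,
) -> tuple[PanelDefinition, PanelDefinition]:
    """Top positively / negatively HOMA-IR-correlated protein panels.

    Immunoglobulin-flagged proteins are excluded; candidates must be
    BH-significant.  Ties in p resolve by |r| descending, then symbol.
    Returns (pro-IR, anti-IR); a shortfall produces a shorter panel with a
    warning.
    """
    corr = homa_correlations.reset_index()
    corr = corr[corr["significant"]]
    ig = {
        g
        for g in corr["gene_symbol"]
        if g in annotations.data.index and annotations.data.loc[g, "immunoglobulin"]
    }
    if ig:
        logger.info("excluding immunoglobulin chain(s) %s from IR panels", sorted(ig))
    corr = corr[~corr["gene_symbol"].isin(ig)]
    corr = corr.sort_values(
        by=["p", "r", "gene_symbol"],
        key=lambda s: -s.abs() if s.name == "r" else s,
    )
    pos = corr[corr["r"] > 0]["gene_symbol"].tolist()[:k_pos]
    neg = corr[corr["r"] < 0]["gene_symbol"].tolist()[:k_neg]
    if len(pos) < k_pos or len(neg) < k_neg:
        logger.warning(
            "IR panels short of target size: %d positive, %d negative", len(pos), len(neg)
        )
    pro = PanelDefinition(
        name="pro_IR",
        members=tuple(pos),
        orientation=tuple((m, 1) for m in pos),
        provenance=(f"top {len(pos)} positive HOMA-IR correlations",),
    )
    anti = PanelDefinition(
        name="anti_IR",
        members=tuple(neg),
        orientation=tuple((m, -1) for m in neg),
        provenance=(f"top {len(neg)} negative HOMA-IR correlations",),
    )
    return pro, anti


def _panel_feature_matrix(
    agg: AggregatedMatrix, panel: PanelDefinition
) -> pd.DataFrame:
    """Individuals x (member, week) features: z across individuals per week."""
    feats = {}
    for member in panel.members:
        accs = _member_accessions(agg, member)
        if not accs:
            continue
        values = agg.values.loc[accs].mean(axis=0).unstack(level="week")
        for week in values.columns:
            z = _zscore_series(values[week])
            feats[(member, week)] = z
    return pd.DataFrame(feats)


def stratify_burden(
    agg: AggregatedMatrix,
    inflammation_panel: PanelDefinition,
    pro_panel: PanelDefinition,
    anti_panel: PanelDefinition,
    min_individuals: int = 4,
    min_weeks: int = MIN_PANEL_WEEKS,
) -> pd.DataFrame:
    """Two-group splits into high-IR / high-inflammation; their intersection
    is the high-metabolic-burden group.

    Features are per-week across-individual z-scores of the panel members
    (missing features mean-imputed to 0 for the split).  Each split is a
    deterministic two-cluster cut of a Ward-linkage tree; the "high" side
    is the cluster with the greater mean oriented panel score.  Only
    individuals observed in at least ``min_weeks`` weeks take part (this
    keeps weight-loss-only dropouts out of the stratification).  If all
    individuals are identical the split is degenerate: everyone is labeled
    low (flagged in the result).
    """
    weeks_per_ind = (
        agg.values.notna().any(axis=0).groupby(level="individual_id").sum()
    )
    individuals = sorted(weeks_per_ind.index[weeks_per_ind >= min_weeks])
    if len(individuals) < min_individuals:
        raise ValidationError(f"stratification needs >= {min_individuals} individuals")

    infl_feat = _panel_feature_matrix(agg, inflammation_panel)
    ir_feat = pd.concat(
        [_panel_feature_matrix(agg, pro_panel), _panel_feature_matrix(agg, anti_panel)],
        axis=1,
    )
    scores = pd.DataFrame(index=pd.Index(individuals, name="individual_id"))
    scores["inflammation_score"] = infl_feat.mean(axis=1)
    pro_feat = _panel_feature_matrix(agg, pro_panel)
    anti_feat = _panel_feature_matrix(agg, anti_panel)
    scores["pro_ir_score"] = pro_feat.mean(axis=1)
    scores["anti_ir_score"] = anti_feat.mean(axis=1)

    def _split(features: pd.DataFrame, score: pd.Series) -> tuple[pd.Series, bool]:
        x = features.reindex(individuals).fillna(0.0).to_numpy()
        if len(individuals) < 2 or np.max(pdist(x), initial=0.0) == 0.0:
            return pd.Series(False, index=individuals), True
        labels = fcluster(linkage(x, method="ward"), t=2, criterion="maxclust")
        labels = pd.Series(labels, index=individuals)
        mean_by = score.groupby(labels).mean()
        if mean_by.nunique() == 1:
            return pd.Series(False, index=individuals), True
        high_label = mean_by.idxmax()
        return labels == high_label, False

    ir_orient = scores["pro_ir_score"].fillna(0.0) - scores["anti_ir_score"].fillna(0.0)
    high_ir, degenerate_ir = _split(ir_feat, ir_orient)
    high_infl, degenerate_infl = _split(
        infl_feat, scores["inflammation_score"].fillna(0.0)
    )
    if degenerate_ir or degenerate_infl:
        logger.warning("degenerate burden split: all individuals labeled low")
    scores["high_IR"] = high_ir
    scores["high_inflammation"] = high_infl
    scores["high_burden"] = high_ir & high_infl
    scores["degenerate_split"] = degenerate_ir or degenerate_infl
    return scores
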