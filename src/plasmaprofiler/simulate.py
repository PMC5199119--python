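"""Synthetic longitudinal plasma-proteome cohorts with a ground-truth ledger.

The generator emulates the statistical structure the analysis stages
assume, so that every stage can be tested by parameter recovery without
any external data:

* individual-specific log-normal baselines (log2 intensity
  ``x = mu_p + b_{p,i} + delta_p * g_a(t) * m_i + e + eps``),
* seven weight-loss trajectory archetypes ``g_a(t)`` in [0, 1] plus a null,
* quadruplicate technical noise whose sd shrinks with abundance
  (counting-type LFQ noise),
* abundance-dependent (MNAR) missingness ``P(missing) = logistic(alpha -
  beta * x)``,
* planted erythrocyte-lysis and coagulation QC failures,
* clinical covariates with planted protein correlations, and
* a named-protein roster carrying the study's published effect sizes.

Each logical entity (protein, individual, clinical variable) draws from
its own pseudo-random stream keyed by ``(seed, kind, index)``, so growing
``n_proteins`` never reshuffles earlier entities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .model import (
    MAINTENANCE_WEEKS,
    WEEKS,
    AnnotationTable,
    ClinicalTable,
    IntensityMatrix,
    ValidationError,
    make_sample_table,
)

#: Trajectory archetype shapes g_a(t) on the seven-week schedule, each in
#: [0, 1] with g(-8) = 0; the sign of the planted effect is part of the
#: archetype so that every archetype maps to one direction of regulation.
ARCHETYPE_SHAPES: dict[str, np.ndarray] = {
    "null": np.zeros(7),
    "down_recover": np.array([0, 1, 0.7, 0.45, 0.25, 0.1, 0.0]),
    "down_hold": np.array([0, 1, 1, 1, 1, 1, 1.0]),
    "up_decline": np.array([0, 1, 0.8, 0.6, 0.45, 0.3, 0.2]),
    "down_slow": np.array([0, 0.3, 0.5, 0.7, 0.85, 1, 1.0]),
    "up_hold": np.array([0, 1, 1, 1, 1, 1, 1.0]),
    "up_slow": np.array([0, 0.3, 0.5, 0.7, 0.85, 1, 1.0]),
    "down_transient": np.array([0, 1, 0.15, 0, 0, 0, 0.0]),
}

ARCHETYPE_SIGNS: dict[str, int] = {
    "null": 0,
    "down_recover": -1,
    "down_hold": -1,
    "up_decline": 1,
    "down_slow": -1,
    "up_hold": 1,
    "up_slow": 1,
    "down_transient": -1,
}

#: Weight-regain multiplier profile applied to non-improver individuals:
#: the week-0 response is intact but decays back as weight is regained.
REGAIN_PROFILE = np.array([1, 1, 0.6, 0.3, 0.1, 0, 0.0])

_DEF_ARCHETYPE_PROBS: dict[str, float] = {
    "null": 0.72,
    "down_recover": 0.04,
    "down_hold": 0.04,
    "up_decline": 0.04,
    "down_slow": 0.04,
    "up_hold": 0.04,
    "up_slow": 0.04,
    "down_transient": 0.04,
}

_STREAM_KIND = {"protein": 1, "individual": 2, "clinical": 3, "qc": 4, "cohort": 5}

LAB_VARIABLES = (
    "HDL", "LDL", "cholesterol", "triglycerides", "glucose", "leptin", "HOMA-IR",
)
_LAB_UNITS: dict[str, tuple[float, float]] = {
    # (center, scale) for mapping standardized composites to plausible units
    "HDL": (1.3, 0.3),
    "LDL": (3.0, 0.8),
    "cholesterol": (5.0, 1.0),
    "triglycerides": (1.6, 0.5),
    "glucose": (5.6, 0.5),
    "leptin": (32.0, 10.0),
    "HOMA-IR": (3.5, 1.3),
}


@dataclass
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults mirror the study design: 52 enrolled individuals of whom 43
    complete the weight-maintenance year (9 dropouts sampled only at weeks
    -8 and 0), seven time points, quadruplicate MS runs per plasma sample,
    and an 18-run matching library counted in the run bookkeeping.
    """

    n_individuals: int = 43          # completers followed across all weeks
    n_dropouts: int = 9              # sampled only at weeks <= 0
    weeks: tuple[int, ...] = WEEKS
    n_replicates: int = 4
    n_proteins: int = 500
    n_library_runs: int = 18         # matching-library runs (bookkeeping only)

    baseline_log2_range: tuple[float, float] = (18.0, 28.5)
    roster_log2_range: tuple[float, float] = (26.0, 29.0)
    sigma_b_range: tuple[float, float] = (0.15, 1.05)
    sigma_w: float = 0.12
    #: technical replicate sd interpolated between these bounds from high
    #: to low abundance over ``baseline_log2_range``
    sigma_t_range: tuple[float, float] = (0.15, 0.60)

    missing_alpha: float = 11.6
    missing_beta: float = 0.675

    include_roster: bool = True
    archetype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_ARCHETYPE_PROBS)
    )
    down_pct_range: tuple[float, float] = (12.0, 45.0)
    up_pct_range: tuple[float, float] = (12.0, 90.0)

    #: Planted individual-specific proteins: one individual carries a fixed
    #: offset chosen clearly beyond the 5x classification cutoff even after
    #: the log-normal cohort mean inflates the denominator (the published
    #: examples reach 10-26-fold).
    n_planted_specific: int = 10     # filler proteins with a planted offset
    specific_offset_log2: float = 3.5
    specific_sigma_w: float = 0.05

    n_lysis_runs: int = 1
    lysis_shift_log2: float = 4.0
    n_coagulation_runs: int = 5
    coagulation_shift_log2: float = -3.0

    n_non_improvers: int = 3         # completers that regain weight
    burden_fraction: float = 14 / 43  # high metabolic burden sub-group
    burden_shift_sd: float = 1.5     # offset shift in units of sigma_b

    bmi_range: tuple[float, float] = (30.0, 40.0)
    bmi_drop_fraction: float = 0.12
    bmi_noise_sd: float = 0.3
    clinical_links: Mapping[str, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in reference.CLINICAL_LINKS.items()}
    )

    seed: int = 0

    def validate(self) -> None:
        if self.sigma_w < 0 or min(self.sigma_t_range) < 0 or min(self.sigma_b_range) < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.n_individuals < 1 or self.n_proteins < 1 or self.n_replicates < 1:
            raise ValidationError("cohort dimensions must be positive")
        probs = dict(self.archetype_probs)
        unknown = set(probs) - set(ARCHETYPE_SHAPES)
        if unknown:
            raise ValidationError(f"unknown archetypes {sorted(unknown)}")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValidationError("archetype probabilities must be >= 0 and sum to 1")
        for var, links in self.clinical_links.items():
            # Joint feasibility depends on the realized signal correlation
            # matrix and is checked (with shrinkage) at generation time;
            # here only the per-protein bound is enforceable.
            if any(abs(r) >= 1.0 for _, r in links):
                raise ValidationError(f"target correlations for {var!r} must be < 1")
        if not set(self.weeks) <= set(WEEKS):
            raise ValidationError(f"weeks must come from the schedule {WEEKS}")
        if self.n_non_improvers > self.n_individuals:
            raise ValidationError("more non-improvers than completers")
        if not 0.0 <= self.burden_fraction <= 1.0:
            raise ValidationError("burden_fraction must lie in [0, 1]")

    # -- design arithmetic -------------------------------------------------

    def design_counts(self) -> dict[str, int]:
        """Sample/run bookkeeping implied by the printed study design."""
        early = sum(1 for w in self.weeks if w <= 0)
        late = sum(1 for w in self.weeks if w > 0)
        n_total = self.n_individuals + self.n_dropouts
        samples = n_total * early + self.n_individuals * late
        quad_runs = samples * self.n_replicates
        return {
            "n_samples": samples,
            "n_quadruplicate_runs": quad_runs,
            "n_library_runs": self.n_library_runs,
            "n_proteomes_total": quad_runs + self.n_library_runs,
        }


@dataclass
class SyntheticTruth:
    """Ground-truth ledger covering every generated protein, individual and run."""

    proteins: pd.DataFrame      # archetype, delta_log2, sigmas, links, planting
    offsets: pd.DataFrame       # b_{p,i}: proteins x individuals (log2)
    individuals: pd.DataFrame   # completer / improver / high_burden flags, BMI base
    runs: pd.DataFrame          # planted lysis / coagulation flags per run
    config: CohortConfig


@dataclass
class SyntheticCohort:
    matrix: IntensityMatrix
    clinical: ClinicalTable
    annotations: AnnotationTable
    truth: SyntheticTruth

    def __iter__(self):  # allow tuple unpacking
        return iter((self.matrix, self.clinical, self.annotations, self.truth))


def _rng(seed: int, kind: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM_KIND[kind], index])


def _sigma_t(mu: float, config: CohortConfig) -> float:
    lo, hi = config.baseline_log2_range
    s_hi, s_lo = config.sigma_t_range  # (at high abundance, at low abundance)
    frac = np.clip((hi - mu) / (hi - lo), 0.0, 1.0)
    return s_hi + (s_lo - s_hi) * frac


def _run_label(individual: str, week: int, replicate: int) -> str:
    wk = f"m{-week}" if week < 0 else str(week)
    return f"{individual}_w{wk}_r{replicate}"


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate one synthetic cohort under ``config`` (defaults = study design)."""
    config = config or CohortConfig()
    config.validate()

    weeks = list(config.weeks)
    week_pos = [WEEKS.index(w) for w in weeks]
    n_weeks = len(weeks)
    R = config.n_replicates
    completers = [f"P{i + 1:02d}" for i in range(config.n_individuals)]
    dropouts = [
        f"P{i + 1:02d}"
        for i in range(config.n_individuals, config.n_individuals + config.n_dropouts)
    ]
    individuals = completers + dropouts
    n_ind = len(individuals)
    early_weeks = [w for w in weeks if w <= 0]

    # ---- individual-level structure -------------------------------------
    rng_cohort = _rng(config.seed, "cohort")
    non_improvers = (
        sorted(
            rng_cohort.choice(config.n_individuals, config.n_non_improvers, replace=False)
        )
        if config.n_non_improvers
        else []
    )
    n_burden = int(round(config.burden_fraction * config.n_individuals))
    burden_ids = (
        sorted(rng_cohort.choice(config.n_individuals, n_burden, replace=False))
        if n_burden
        else []
    )
    improver = np.ones(n_ind, dtype=bool)
    improver[list(non_improvers)] = False
    burden = np.zeros(n_ind, dtype=bool)
    burden[list(burden_ids)] = True

    bmi0 = np.empty(n_ind)
    height = np.empty(n_ind)
    for i in range(n_ind):
        r = _rng(config.seed, "individual", i)
        bmi0[i] = r.uniform(*config.bmi_range)
        height[i] = r.normal(1.72, 0.09)

    # per-individual weight trajectory multiplier (1 - drop * shape)
    hold = ARCHETYPE_SHAPES["down_hold"][week_pos]
    regain = REGAIN_PROFILE[week_pos]
    weight_shape = np.empty((n_ind, n_weeks))
    for i in range(n_ind):
        shape = hold * (regain if not improver[i] else 1.0)
        weight_shape[i] = 1.0 - config.bmi_drop_fraction * shape

    # ---- protein roster + fillers ---------------------------------------
    roster = reference.build_roster() if config.include_roster else []
    if config.n_proteins < len(roster):
        roster = roster[: config.n_proteins]
    n_filler = config.n_proteins - len(roster)
    arch_names = list(config.archetype_probs)
    arch_p = np.array([config.archetype_probs[a] for a in arch_names])

    burden_orient: dict[str, int] = {}
    if config.include_roster:
        for g in reference.INFLAMMATION_KEYWORD_GENES + reference.INFLAMMATION_ADDED_GENES:
            burden_orient[g] = 1
        for g in reference.PRO_IR_GENES:
            burden_orient[g] = 1
        for g in reference.ANTI_IR_GENES:
            burden_orient[g] = -1

    genes: list[str] = []
    accs: list[str] = []
    mu = np.empty(config.n_proteins)
    sigma_b = np.empty(config.n_proteins)
    sigma_w = np.empty(config.n_proteins)
    sigma_t = np.empty(config.n_proteins)
    archetype: list[str] = []
    delta = np.zeros(config.n_proteins)
    specific_individual = np.full(config.n_proteins, -1)
    specific_offset = np.zeros(config.n_proteins)

    b = np.empty((config.n_proteins, n_ind))
    e = np.empty((config.n_proteins, n_ind, n_weeks))
    eps = np.empty((config.n_proteins, n_ind, n_weeks, R))
    u_miss = np.empty((config.n_proteins, n_ind, n_weeks, R))

    n_specific_planted = 0
    for p in range(config.n_proteins):
        r = _rng(config.seed, "protein", p)
        if p < len(roster):
            rp = roster[p]
            gene = rp.gene
            m = r.uniform(*config.roster_log2_range)
            if rp.mu_log2 is not None:
                m = rp.mu_log2
            sb = rp.sigma_b if rp.sigma_b is not None else r.uniform(*config.sigma_b_range)
            sw = rp.sigma_w if rp.sigma_w is not None else config.sigma_w
            arch = rp.archetype
            d = np.log2(1.0 + rp.pct_change / 100.0) if rp.pct_change else 0.0
            spec_off = rp.specific_offset_log2
        else:
            gene = f"PROT{p:04d}"
            m = r.uniform(*config.baseline_log2_range)
            sb = r.uniform(*config.sigma_b_range)
            sw = config.sigma_w
            arch = arch_names[r.choice(len(arch_names), p=arch_p)]
            sign = ARCHETYPE_SIGNS[arch]
            if sign > 0:
                d = np.log2(1.0 + r.uniform(*config.up_pct_range) / 100.0)
            elif sign < 0:
                d = np.log2(1.0 - r.uniform(*config.down_pct_range) / 100.0)
            else:
                d = 0.0
            spec_off = None
            if (
                arch == "null"
                and n_specific_planted < config.n_planted_specific
            ):
                spec_off = config.specific_offset_log2
                sw = config.specific_sigma_w
                # plant at abundances where technical noise keeps the
                # longitudinal CV below the individual-specific gate
                lo, hi = config.baseline_log2_range
                m = r.uniform(max(lo, hi - 5.0), hi)
                n_specific_planted += 1
        genes.append(gene)
        accs.append(f"ACC{p:04d}")
        mu[p], sigma_b[p], sigma_w[p] = m, sb, sw
        sigma_t[p] = _sigma_t(m, config)
        archetype.append(arch)
        delta[p] = d
        b[p] = r.normal(0.0, sb, n_ind)
        if spec_off is not None:
            idx = int(r.integers(0, config.n_individuals))
            specific_individual[p] = idx
            specific_offset[p] = spec_off
            b[p, idx] = spec_off
        e[p] = r.normal(0.0, sw, (n_ind, n_weeks))
        eps[p] = r.normal(0.0, sigma_t[p], (n_ind, n_weeks, R))
        u_miss[p] = r.uniform(size=(n_ind, n_weeks, R))

    # high-metabolic-burden offset shifts on panel-role proteins
    for p, gene in enumerate(genes):
        orient = burden_orient.get(gene)
        if orient:
            b[p, burden] += orient * config.burden_shift_sd * sigma_b[p]

    # ---- assemble log2 signal -------------------------------------------
    g_mat = np.stack([ARCHETYPE_SHAPES[a][week_pos] for a in archetype])  # (P, T)
    mod = np.where(improver[:, None], 1.0, regain[None, :])  # (I, T)
    effect = delta[:, None, None] * g_mat[:, None, :] * mod[None, :, :]
    signal = mu[:, None, None] + b[:, :, None] + effect + e  # (P, I, T)
    x = signal[..., None] + eps  # (P, I, T, R)

    # MNAR thinning on the realized replicate log2 intensity
    p_miss = 1.0 / (1.0 + np.exp(-(config.missing_alpha - config.missing_beta * x)))
    missing = u_miss < p_miss

    # ---- runs and QC planting -------------------------------------------
    run_index: list[tuple[int, int, int]] = []  # (individual idx, week idx, replicate)
    records = []
    for i, ind in enumerate(individuals):
        ind_weeks = weeks if ind in completers else early_weeks
        for w in ind_weeks:
            t = weeks.index(w)
            for rep in range(1, R + 1):
                run_index.append((i, t, rep - 1))
                records.append(
                    {
                        "run_label": _run_label(ind, w, rep),
                        "individual_id": ind,
                        "week": w,
                        "replicate": rep,
                    }
                )
    samples = make_sample_table(pd.DataFrame(records))
    n_runs = len(run_index)

    rng_qc = _rng(config.seed, "qc")
    n_qc = config.n_lysis_runs + config.n_coagulation_runs
    qc_runs = rng_qc.choice(n_runs, size=min(n_qc, n_runs), replace=False)
    lysis_runs = set(qc_runs[: config.n_lysis_runs].tolist())
    coag_runs = set(qc_runs[config.n_lysis_runs:].tolist())

    ery_rows = [p for p, g in enumerate(genes) if g in reference.ERYTHROCYTE_MARKER_GENES]
    fib_rows = [p for p, g in enumerate(genes) if g in reference.FIBRINOGEN_GENES]

    values = np.empty((config.n_proteins, n_runs))
    for col, (i, t, rep) in enumerate(run_index):
        v = x[:, i, t, rep].copy()
        if col in lysis_runs and ery_rows:
            v[ery_rows] += config.lysis_shift_log2
        if col in coag_runs and fib_rows:
            v[fib_rows] += config.coagulation_shift_log2
        v[missing[:, i, t, rep]] = np.nan
        values[:, col] = v

    values_df = pd.DataFrame(
        np.power(2.0, values),
        index=pd.Index(accs, name="accession"),
        columns=samples.index,
    )
    proteins_df = pd.DataFrame(
        {
            "gene_symbol": genes,
            "is_contaminant": False,
            "is_reverse": False,
        },
        index=values_df.index,
    )

    # ---- clinical table --------------------------------------------------
    gene_to_row = {g: p for p, g in enumerate(genes)}
    clin_rows: dict[tuple[str, int], dict[str, float]] = {}
    for i, ind in enumerate(individuals):
        ind_weeks = weeks if ind in completers else early_weeks
        r = _rng(config.seed, "clinical", i)
        for w in ind_weeks:
            t = weeks.index(w)
            bmi = bmi0[i] * weight_shape[i, t] + r.normal(0.0, config.bmi_noise_sd)
            clin_rows[(ind, w)] = {
                "BMI": bmi,
                "weight": bmi * height[i] ** 2,
            }

    lab_weeks = [w for w in (-8, 0, 52) if w in weeks]
    lab_pairs = [
        (i, weeks.index(w))
        for i, ind in enumerate(individuals)
        for w in (weeks if ind in completers else early_weeks)
        if w in lab_weeks
    ]
    if lab_pairs and config.clinical_links is not None:
        rng_lab = _rng(config.seed, "clinical", n_ind + 1)
        ii = np.array([p[0] for p in lab_pairs])
        tt = np.array([p[1] for p in lab_pairs])
        # aggregated measured log2 values (median over replicates) at the
        # lab-week (individual, week) pairs, per linked protein
        run_pair_index = pd.MultiIndex.from_arrays(
            [[i for (i, _, _) in run_index], [t for (_, t, _) in run_index]]
        )
        log2_measured = np.log2(values_df.to_numpy())

        def _measured_z(row: int) -> np.ndarray:
            s = (
                pd.Series(log2_measured[row], index=run_pair_index)
                .groupby(level=[0, 1])
                .median()
            )
            pairs = pd.MultiIndex.from_arrays([ii, tt])
            x = s.reindex(pairs).to_numpy()
            mu_x = np.nanmean(x)
            sd_x = np.nanstd(x)
            if not np.isfinite(sd_x) or sd_x == 0:
                return np.zeros(len(pairs))
            z = (x - mu_x) / sd_x
            return np.where(np.isfinite(z), z, 0.0)

        for var in LAB_VARIABLES:
            links = [
                (g, r) for g, r in config.clinical_links.get(var, ())
                if g in gene_to_row
            ]
            if links:
                # Weighted composite of the standardized *measured* protein
                # levels (so the targets are not attenuated by technical
                # noise).  Linked proteins are correlated (shared
                # archetypes, burden shifts), so the weights solve
                # w = C^-1 r against the empirical correlation matrix: each
                # protein then correlates with the variable at its target r.
                Z = np.column_stack(
                    [_measured_z(gene_to_row[g]) for g, _ in links]
                )
                r_vec = np.array([r for _, r in links])
                C = np.corrcoef(Z, rowvar=False)
                C = np.atleast_2d(C) + 1e-8 * np.eye(len(links))
                w = np.linalg.solve(C, r_vec)
                quad = float(r_vec @ w)
                if quad > 0.9:
                    shrink = np.sqrt(0.9 / quad)
                    logger_msg = (
                        f"targets for {var} jointly infeasible; scaled by {shrink:.3f}"
                    )
                    import logging as _logging

                    _logging.getLogger(__name__).warning(logger_msg)
                    r_vec = r_vec * shrink
                    w = w * shrink
                    quad = 0.9
                tau = np.sqrt(1.0 - quad)
                v0 = Z @ w + tau * rng_lab.normal(size=len(lab_pairs))
            else:
                v0 = rng_lab.normal(size=len(lab_pairs))
            center, scale = _LAB_UNITS[var]
            vals = np.maximum(center + scale * v0, 0.1)
            for k, (i, t) in enumerate(lab_pairs):
                clin_rows[(individuals[i], weeks[t])][var] = vals[k]

    # BMI-linked proteins: BMI itself keeps its designed drop-and-hold
    # curve, so the link is realized by injecting standardized BMI into the
    # linked protein's measured values (same joint law as building the
    # variable from the protein signal plus noise).
    bmi_links = list(config.clinical_links.get("BMI", ())) if config.clinical_links else []
    if bmi_links:
        run_pairs = pd.MultiIndex.from_arrays(
            [[individuals[i] for (i, _, _) in run_index],
             [weeks[t] for (_, t, _) in run_index]]
        )
        bmi_by_pair = pd.Series(
            {key: vals["BMI"] for key, vals in clin_rows.items()}
        )
        y_pair = (bmi_by_pair - bmi_by_pair.mean()) / bmi_by_pair.std(ddof=0)
        y_run = y_pair.loc[run_pairs].to_numpy()
        log2v = np.log2(values_df.to_numpy())
        for gene, r_target in bmi_links:
            row = gene_to_row.get(gene)
            if row is None:
                continue
            # Solve the injection coefficient kappa from the protein's
            # empirical covariance with BMI at the aggregated level, so the
            # realized (individual, week)-level correlation hits the target
            # even when chance between-individual association works against it.
            x_agg = pd.Series(log2v[row], index=run_pairs).groupby(level=[0, 1]).median()
            joined = pd.concat([x_agg, y_pair], axis=1, keys=["x", "y"]).dropna()
            s2 = float(joined["x"].var(ddof=0))
            cxy = float(np.cov(joined["x"], joined["y"], ddof=0)[0, 1])
            resid = s2 - cxy * cxy
            if resid <= 0:
                continue
            u = r_target * np.sqrt(resid / (1.0 - r_target**2))
            kappa = u - cxy
            log2v[row] += kappa * y_run
        values_df = pd.DataFrame(
            np.power(2.0, log2v), index=values_df.index, columns=values_df.columns
        )

    matrix = IntensityMatrix(values=values_df, proteins=proteins_df, samples=samples)

    clinical = ClinicalTable(
        data=pd.DataFrame.from_dict(clin_rows, orient="index").rename_axis(
            ["individual_id", "week"]
        ).sort_index()
    )

    # ---- annotations -----------------------------------------------------
    if config.include_roster:
        ann = reference.roster_annotation_frame()
        filler = pd.DataFrame(
            {
                "keywords": [frozenset()] * n_filler,
                "gocc": [frozenset()] * n_filler,
                "gobp": [frozenset()] * n_filler,
                "erythrocyte_marker": False,
                "fibrinogen": False,
                "immunoglobulin": False,
            },
            index=pd.Index(genes[len(roster):], name="gene_symbol"),
        )
        ann = pd.concat([ann.loc[[r.gene for r in roster]], filler])
    else:
        ann = pd.DataFrame(
            {
                "keywords": [frozenset()] * len(genes),
                "gocc": [frozenset()] * len(genes),
                "gobp": [frozenset()] * len(genes),
                "erythrocyte_marker": False,
                "fibrinogen": False,
                "immunoglobulin": False,
            },
            index=pd.Index(genes, name="gene_symbol"),
        )
    annotations = AnnotationTable(data=ann)

    # ---- truth ledger ----------------------------------------------------
    linked_var = [""] * config.n_proteins
    linked_r = [np.nan] * config.n_proteins
    if config.clinical_links:
        for var, links in config.clinical_links.items():
            for gene, r_target in links:
                row = gene_to_row.get(gene)
                if row is not None:
                    linked_var[row] = var
                    linked_r[row] = r_target
    truth_proteins = pd.DataFrame(
        {
            "gene_symbol": genes,
            "archetype": archetype,
            "delta_log2": delta,
            "sigma_b": sigma_b,
            "sigma_w": sigma_w,
            "sigma_t": sigma_t,
            "mu_log2": mu,
            "linked_variable": linked_var,
            "target_r": linked_r,
            "specific_individual": [
                individuals[i] if i >= 0 else "" for i in specific_individual
            ],
            "specific_offset_log2": specific_offset,
        },
        index=values_df.index,
    )
    truth_individuals = pd.DataFrame(
        {
            "completer": [ind in completers for ind in individuals],
            "improver": improver,
            "high_burden": burden,
            "baseline_bmi": bmi0,
        },
        index=pd.Index(individuals, name="individual_id"),
    )
    truth_runs = pd.DataFrame(
        {
            "lysis": [col in lysis_runs for col in range(n_runs)],
            "coagulation": [col in coag_runs for col in range(n_runs)],
        },
        index=samples.index,
    )
    truth_offsets = pd.DataFrame(b, index=values_df.index, columns=individuals)
    truth = SyntheticTruth(
        proteins=truth_proteins,
        offsets=truth_offsets,
        individuals=truth_individuals,
        runs=truth_runs,
        config=config,
    )
    return SyntheticCohort(matrix, clinical, annotations, truth)


# -- fixtures -------------------------------------------------------------


def emit_fixture_suite(outdir: str | Path, seed: int = 20160) -> dict[str, Path]:
    """Write the small deterministic fixtures used by the unit tests.

    Produces: a toy plain matrix with one literal zero, a small
    proteingroups-dialect file with a contaminant row, the reference
    annotation table, the BMI-correlation reference table used by the
    panel-selection worked example, and a small clinical table.
    """
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # toy plain matrix (3 proteins x 2 runs, one zero -> missing)
    toy = outdir / "toy_matrix.tsv"
    toy.write_text(
        "accession\tgene_symbol\tS1_wm8_r1\tS1_wm8_r2\n"
        "A1\tCRP\t100.0\t110.0\n"
        "A2\tALB\t5000.0\t0\n"
        "A3\tAPOB\t800.0\t790.0\n",
        encoding="utf-8",
    )
    paths["toy_matrix"] = toy
    toy_samples = outdir / "toy_samples.tsv"
    toy_samples.write_text(
        "run_label\tindividual_id\tweek\treplicate\n"
        "S1_wm8_r1\tS1\t-8\t1\n"
        "S1_wm8_r2\tS1\t-8\t2\n",
        encoding="utf-8",
    )
    paths["toy_samples"] = toy_samples

    # small proteingroups file derived from a tiny synthetic cohort
    cfg = CohortConfig(
        n_individuals=2, n_dropouts=0, n_proteins=10, seed=seed,
        n_planted_specific=0, n_lysis_runs=0, n_coagulation_runs=0,
        n_non_improvers=0,
    )
    cohort = generate_cohort(cfg)
    mat = cohort.matrix
    con = mat.proteins.copy()
    con.loc[con.index[-1], ["gene_symbol", "is_contaminant"]] = ["KRT1", True]
    vals = mat.values.copy()
    vals.index = pd.Index(
        ["CON__" + a if con.loc[a, "is_contaminant"] else a for a in vals.index],
        name="accession",
    )
    con.index = vals.index
    small = IntensityMatrix(values=vals, proteins=con, samples=mat.samples)
    pg = outdir / "proteingroups_small.txt"
    pio.write_intensity_matrix(small, pg, dialect="proteingroups")
    paths["proteingroups_small"] = pg
    pg_samples = outdir / "proteingroups_small_samples.tsv"
    pio.write_sample_table(mat.samples, pg_samples)
    paths["proteingroups_samples"] = pg_samples

    ann_path = outdir / "annotations_reference.tsv"
    pio.write_annotations(AnnotationTable(data=reference.roster_annotation_frame()), ann_path)
    paths["annotations_reference"] = ann_path

    bmi_path = outdir / "bmi_correlations_reference.tsv"
    reference.bmi_correlation_fixture().to_csv(bmi_path, sep="\t", index=False)
    paths["bmi_correlations_reference"] = bmi_path

    clin_path = outdir / "clinical_small.csv"
    pio.write_clinical_table(cohort.clinical, clin_path)
    paths["clinical_small"] = clin_path
    return paths
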