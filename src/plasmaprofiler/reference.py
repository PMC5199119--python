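"""Reference protein roster: annotations and planted study conditions.

This module collects the named plasma proteins the analysis revolves
around — erythrocyte-lysis and coagulation QC markers, the acute-phase /
inflammation set, the apolipoprotein family with lipoprotein-particle
membership, and insulin-resistance panel candidates — together with the
longitudinal behaviour the synthetic cohort plants for each (trajectory
archetype and percent change at the end of weight loss).

Annotation term sets follow standard UniProt keyword and Gene Ontology
vocabulary.  Effect sizes use published percent changes where a value is
known for the protein; remaining members carry values in the typical
reported range.  The pro-IR panel members are synthetic stand-ins (the
positively-correlating panel is not publicly itemized); the anti-IR list
combines the known members ADIPOQ, NRP1 and APOF with synthetic stand-ins
SHBG and GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ERYTHROCYTE_MARKER_GENES: tuple[str, ...] = ("HBA1", "HBB", "HBD", "CA1")
FIBRINOGEN_GENES: tuple[str, ...] = ("FGA", "FGB", "FGG")

INFLAMMATION_KEYWORDS: tuple[str, ...] = (
    "acute phase",
    "inflammatory response",
    "immunity",
)

#: The five proteins most significantly correlated with BMI, then the five
#: further BMI-correlated inflammation factors; together the ten-protein
#: inflammation panel.
TOP_BMI_GENES: tuple[str, ...] = ("CFH", "C3", "APCS", "ORM2", "CFI")
FURTHER_BMI_GENES: tuple[str, ...] = ("CRP", "SAA4", "ORM1", "ATRN", "CFB")
BMI_PANEL_GENES: tuple[str, ...] = TOP_BMI_GENES + FURTHER_BMI_GENES

C1Q_CHAINS: tuple[str, ...] = ("C1QA", "C1QB", "C1QC")

#: Keyword-annotated members of the weight-loss inflammation screen
#: (C1QA/B/C collapse to a single entry, giving 23 keyword hits).
INFLAMMATION_KEYWORD_GENES: tuple[str, ...] = (
    "CRP", "SAA1", "SAA4", "ORM1", "ORM2",
    "SERPINA1", "SERPINA3", "CD14", "IL1RAP",
    "CFH", "C3", "CFI", "CFB", "ATRN",
    "C4A", "C4B", "C8B", "C8G", "C2", "C5", "C6", "C7",
) + C1Q_CHAINS

#: Acute-phase proteins not keyword-annotated but added to the panel set.
INFLAMMATION_ADDED_GENES: tuple[str, ...] = ("APCS", "LBP")

PRO_IR_GENES: tuple[str, ...] = ("SERPINF1", "FETUB", "PRG4", "SERPIND1")
ANTI_IR_GENES: tuple[str, ...] = ("ADIPOQ", "NRP1", "APOF", "SHBG", "GC")

#: Canonical GOCC lipoprotein-particle term per particle short name.
PARTICLE_TERMS: dict[str, str] = {
    "chylomicron": "chylomicron",
    "HDL": "high-density lipoprotein particle",
    "IDL": "intermediate-density lipoprotein particle",
    "LDL": "low-density lipoprotein particle",
    "vLDL": "very-low-density lipoprotein particle",
}

_GOCC_MEMBERSHIP: dict[str, tuple[str, ...]] = {
    "chylomicron": ("APOA1", "APOA2", "APOA4", "APOB", "APOC2", "APOC3", "APOE"),
    "HDL": (
        "APOA1", "APOA2", "APOA4", "APOC1", "APOC2", "APOC3",
        "APOD", "APOE", "APOF", "APOL1", "APOM", "PON1", "SAA1", "SAA4",
    ),
    "IDL": ("APOB", "APOC2", "APOC3", "APOE"),
    "LDL": ("APOB", "APOE", "LPA"),
    "vLDL": ("APOB", "APOC1", "APOC2", "APOC3", "APOE"),
}

_GOBP_TERMS: dict[str, tuple[str, ...]] = {
    "lipid metabolic process": (
        "APOA1", "APOA2", "APOA4", "APOB", "APOC1", "APOC2", "APOC3",
        "APOC4", "APOD", "APOE", "APOF", "APOL1", "APOM", "LPA", "PON1",
    ),
    "cholesterol transport": ("APOA1", "APOB", "APOE", "APOF"),
    "cholesterol homeostasis": ("APOA1", "APOA2", "APOC2", "APOE"),
    "lipoprotein metabolic process": ("APOB", "APOC2", "APOC3", "APOE", "LPA"),
    "triglyceride homeostasis": ("APOA4", "APOC2", "APOC3"),
    "fatty acid metabolic process": ("APOC2", "APOC3"),
    "acute-phase response": ("CRP", "SAA1", "SAA4", "ORM1", "ORM2", "APCS", "LBP"),
    "complement activation": (
        "C2", "C3", "C4A", "C4B", "C5", "C6", "C7", "C8B", "C8G",
        "CFB", "CFH", "CFI", "C1QA", "C1QB", "C1QC",
    ),
    "blood coagulation": ("FGA", "FGB", "FGG", "SERPIND1", "KNG1"),
    "oxygen transport": ("HBA1", "HBB", "HBD"),
}


@dataclass(frozen=True)
class RosterProtein:
    """One named protein and the longitudinal behaviour planted for it."""

    gene: str
    archetype: str = "null"
    pct_change: float = 0.0  # percent change at week 0 vs week -8
    sigma_b: float | None = None  # between-individual sd override (log2)
    sigma_w: float | None = None  # within-individual sd override (log2)
    mu_log2: float | None = None  # fixed baseline abundance (log2) override
    keywords: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()
    specific_offset_log2: float | None = None  # planted individual-specific offset


def _kw(gene: str) -> tuple[str, ...]:
    """Keyword assignment for the inflammation screen members."""
    table = {
        "CRP": ("acute phase",),
        "SAA1": ("acute phase",),
        "SAA4": ("acute phase",),
        "ORM1": ("acute phase",),
        "ORM2": ("acute phase",),
        "SERPINA1": ("acute phase",),
        "SERPINA3": ("acute phase", "inflammatory response"),
        "CD14": ("inflammatory response", "immunity"),
        "IL1RAP": ("inflammatory response",),
        "CFH": ("immunity", "inflammatory response"),
        "C3": ("immunity", "acute phase"),
        "CFI": ("immunity",),
        "CFB": ("immunity",),
        "ATRN": ("inflammatory response",),
        "C4A": ("immunity",),
        "C4B": ("immunity",),
        "C8B": ("immunity",),
        "C8G": ("immunity",),
        "C2": ("immunity",),
        "C5": ("immunity", "inflammatory response"),
        "C6": ("immunity",),
        "C7": ("immunity",),
        "C1QA": ("immunity",),
        "C1QB": ("immunity",),
        "C1QC": ("immunity",),
    }
    return table[gene]


def build_roster() -> list[RosterProtein]:
    """Full named-protein roster with planted study conditions."""
    roster: list[RosterProtein] = []

    # QC marker proteins: biologically stable, high abundance.
    ery_mu = {"HBA1": 29.5, "HBB": 29.7, "HBD": 28.5, "CA1": 28.0}
    for g in ERYTHROCYTE_MARKER_GENES:
        roster.append(
            RosterProtein(g, sigma_b=0.3, mu_log2=ery_mu[g],
                          flags=("erythrocyte_marker",))
        )
    fib_mu = {"FGA": 30.2, "FGB": 30.0, "FGG": 29.8}
    for g in FIBRINOGEN_GENES:
        roster.append(
            RosterProtein(g, sigma_b=0.3, mu_log2=fib_mu[g], flags=("fibrinogen",))
        )

    # Inflammation screen members (keyword-annotated).
    infl = {
        "CRP": ("down_hold", -35.0), "SAA1": ("down_hold", -43.0),
        "SAA4": ("down_hold", -30.0), "ORM2": ("down_hold", -25.0),
        "ORM1": ("down_slow", -16.0), "SERPINA1": ("up_decline", 15.0),
        "SERPINA3": ("up_decline", 18.0), "CD14": ("up_decline", 25.0),
        "IL1RAP": ("up_decline", 67.0), "CFH": ("down_slow", -15.0),
        "C3": ("down_hold", -12.0), "CFI": ("down_slow", -14.0),
        "CFB": ("down_hold", -15.0), "ATRN": ("down_hold", -13.0),
        "C4A": ("down_slow", -12.0), "C4B": ("down_slow", -12.0),
        "C8B": ("down_slow", -11.0), "C8G": ("down_slow", -11.0),
        "C2": ("down_slow", -10.0), "C5": ("down_hold", -11.0),
        "C6": ("down_slow", -10.0), "C7": ("down_slow", -12.0),
        "C1QA": ("down_hold", -12.0), "C1QB": ("down_hold", -12.0),
        "C1QC": ("down_hold", -12.0),
    }
    tight = {"C3": 0.12, "CFH": 0.12}  # tightly controlled despite responding
    for g, (arch, pct) in infl.items():
        roster.append(
            RosterProtein(g, arch, pct, sigma_b=tight.get(g, 0.5), keywords=_kw(g))
        )

    # Non-annotated acute-phase additions.
    roster.append(RosterProtein("APCS", "down_slow", -10.0, sigma_b=0.4))
    roster.append(RosterProtein("LBP", "down_slow", -16.0, sigma_b=0.5))

    # Apolipoprotein family (APOB -10% vs APOA1 -2% gives an -8% APOB/APOA1
    # ratio change at week 0).
    apos = {
        "APOA1": ("down_hold", -2.0), "APOA2": ("down_hold", -12.0),
        "APOA4": ("down_recover", -36.0), "APOB": ("down_hold", -10.0),
        "APOC1": ("down_hold", -30.0), "APOC2": ("down_hold", -28.0),
        "APOC3": ("down_hold", -30.0), "APOC4": ("down_hold", -27.0),
        "APOD": ("null", 0.0), "APOE": ("down_hold", -15.0),
        "APOF": ("up_decline", 37.0), "APOL1": ("down_slow", -12.0),
        "APOM": ("down_slow", -10.0), "LPA": ("up_decline", 95.0),
        "PON1": ("down_recover", -20.0), "AFM": ("down_recover", -15.0),
    }
    apo_mu = {"APOA1": 30.5, "APOA2": 29.6, "APOB": 30.0}  # most abundant apos
    for g, (arch, pct) in apos.items():
        sb = 1.5 if g == "LPA" else 0.5  # LPA spans orders of magnitude
        roster.append(RosterProtein(g, arch, pct, sigma_b=sb, mu_log2=apo_mu.get(g)))

    # Insulin-resistance panel candidates and other named proteins.
    roster += [
        RosterProtein("SERPINF1", "down_hold", -16.0, sigma_b=0.4),
        RosterProtein("FETUB", "down_slow", -12.0, sigma_b=0.6),
        RosterProtein("PRG4", "down_hold", -19.0, sigma_b=0.5),
        RosterProtein("SERPIND1", "down_slow", -9.0, sigma_b=0.4),
        RosterProtein("ADIPOQ", "up_hold", 15.0, sigma_b=0.5),
        RosterProtein("NRP1", "up_slow", 90.0, sigma_b=0.5),
        RosterProtein("SHBG", "up_hold", 117.0, sigma_b=0.8),
        RosterProtein("GC", "up_hold", 12.0, sigma_b=0.10),
        RosterProtein("ALB", "up_hold", 8.0, sigma_b=0.08, mu_log2=31.0),
        RosterProtein("KNG1", "null", 0.0, sigma_b=0.10),
        RosterProtein("HPX", "null", 0.0, sigma_b=0.10),
        RosterProtein("CLU", "null", 0.0, sigma_b=0.10),
        RosterProtein("A2M", "null", 0.0, sigma_b=1.2, sigma_w=0.06, mu_log2=30.0),
        RosterProtein("PZP", "null", 0.0, sigma_b=0.6, sigma_w=0.06,
                      specific_offset_log2=6.0),
        RosterProtein("IGHG1", "null", 0.0, sigma_b=0.5, flags=("immunoglobulin",)),
        RosterProtein("IGJ", "null", 0.0, sigma_b=0.6, flags=("immunoglobulin",)),
    ]
    genes = [r.gene for r in roster]
    assert len(genes) == len(set(genes))
    return roster


def roster_annotation_frame():
    """Annotation rows (keywords, GOCC, GOBP, flags) for the roster genes."""
    import pandas as pd

    roster = build_roster()
    gocc: dict[str, set[str]] = {r.gene: set() for r in roster}
    for particle, members in _GOCC_MEMBERSHIP.items():
        term = PARTICLE_TERMS[particle]
        for g in members:
            if g in gocc:
                gocc[g].add(term)
    gobp: dict[str, set[str]] = {r.gene: set() for r in roster}
    for term, members in _GOBP_TERMS.items():
        for g in members:
            if g in gobp:
                gobp[g].add(term)
    data = pd.DataFrame(
        {
            "keywords": [frozenset(r.keywords) for r in roster],
            "gocc": [frozenset(gocc[r.gene]) for r in roster],
            "gobp": [frozenset(gobp[r.gene]) for r in roster],
            "erythrocyte_marker": ["erythrocyte_marker" in r.flags for r in roster],
            "fibrinogen": ["fibrinogen" in r.flags for r in roster],
            "immunoglobulin": ["immunoglobulin" in r.flags for r in roster],
        },
        index=pd.Index([r.gene for r in roster], name="gene_symbol"),
    )
    return data


#: Default clinical linkage: variable -> ((gene, target Pearson r), ...).
#: Weights satisfy sum(r^2) < 1 per variable so each target is attainable
#: with independent protein signals.
CLINICAL_LINKS: dict[str, tuple[tuple[str, float], ...]] = {
    "BMI": (
        ("CFH", 0.45), ("C3", 0.42), ("APCS", 0.40), ("ORM2", 0.38),
        ("CFI", 0.36), ("CRP", 0.33), ("SAA4", 0.32), ("ORM1", 0.31),
        ("ATRN", 0.30), ("CFB", 0.30),
    ),
    "HDL": (
        ("APOA1", 0.60), ("APOD", 0.40), ("PON1", 0.38), ("APOA4", 0.35),
        ("APCS", 0.30),
    ),
    "LDL": (("APOB", 0.70), ("PRG4", 0.45)),
    "cholesterol": (
        ("APOB", 0.45), ("APOC3", 0.40), ("APOE", 0.40), ("APOC2", 0.35),
        ("APOF", 0.30),
    ),
    "triglycerides": (
        ("APOC3", 0.45), ("APOC2", 0.40), ("APOE", 0.35), ("APOB", 0.30),
        ("APOC4", 0.30), ("APOF", -0.45),
    ),
    "glucose": (("C3", 0.25), ("SERPINF1", 0.25)),
    "leptin": (
        ("CRP", 0.35), ("SAA1", 0.30), ("APCS", 0.25), ("C3", 0.25),
        ("CFH", 0.25), ("SAA4", 0.25), ("NRP1", -0.25), ("APOF", -0.25),
    ),
    "HOMA-IR": (
        ("SERPINF1", 0.42), ("FETUB", 0.40), ("PRG4", 0.38), ("SERPIND1", 0.36),
        ("IGHG1", 0.46),
        ("ADIPOQ", -0.44), ("NRP1", -0.40), ("APOF", -0.38), ("SHBG", -0.36),
        ("GC", -0.34),
    ),
}


def bmi_correlation_fixture():
    """Reference BMI-correlation calls for the panel-selection worked example.

    Panel membership (which inflammation-set members are BMI-correlated, and
    the ordering of the top five) is taken from the published analysis; the
    r/p magnitudes are synthetic values in the reported range (r 0.3-0.4,
    p < 1e-8 for the top five).
    """
    import pandas as pd

    rows = []
    top_r = {"CFH": 0.40, "C3": 0.38, "APCS": 0.36, "ORM2": 0.34, "CFI": 0.33}
    top_p = {"CFH": 1e-12, "C3": 5e-12, "APCS": 4e-11, "ORM2": 8e-10, "CFI": 6e-9}
    further_r = {"CRP": 0.30, "SAA4": 0.28, "ORM1": 0.27, "ATRN": 0.26, "CFB": 0.25}
    further_p = {"CRP": 2e-7, "SAA4": 9e-7, "ORM1": 4e-6, "ATRN": 2e-5, "CFB": 9e-5}
    for gene in BMI_PANEL_GENES:
        r = top_r.get(gene, further_r.get(gene))
        p = top_p.get(gene, further_p.get(gene))
        rows.append((gene, "BMI", 301, r, p, True))
    # Non-correlated inflammation-set members and a few other proteins.
    others = {
        "SAA1": (0.12, 0.04), "SERPINA1": (0.05, 0.39), "SERPINA3": (0.07, 0.22),
        "IL1RAP": (-0.06, 0.30), "C4A": (0.10, 0.08), "C4B": (0.09, 0.12),
        "C8B": (0.08, 0.17), "C8G": (0.06, 0.30), "C2": (0.05, 0.39),
        "C5": (0.08, 0.17), "C6": (0.04, 0.49), "C7": (0.06, 0.30),
        "C1QA": (0.07, 0.22), "C1QB": (0.06, 0.30), "C1QC": (0.05, 0.39),
        "LBP": (0.11, 0.06), "APOB": (0.08, 0.17), "ALB": (-0.03, 0.60),
    }
    for gene, (r, p) in others.items():
        rows.append((gene, "BMI", 301, r, p, False))
    df = pd.DataFrame(
        rows, columns=["gene_symbol", "variable", "n", "r", "p", "significant"]
    )
    # Benjamini-Hochberg q-values over this fixture's p-vector.
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(df["p"], alpha=0.05, method="fdr_bh")
    df["q"] = q
    return df
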