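"""Domain types shared by every analysis stage.

The central observable is an :class:`IntensityMatrix`: label-free
quantification (LFQ) intensities for proteins (rows) across MS runs
(columns).  Runs are keyed to ``(individual, week, replicate)`` through a
sample table; clinical covariates and per-protein annotations live in their
own tables.  All intensities are stored on the linear scale with an explicit
missing state (NaN); an LFQ value of zero conventionally means "not
quantified" and is mapped to missing at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sampling schedule in weeks relative to the end of the weight-loss phase
#: (week 0); week -8 is the pre-intervention baseline and weeks 4..52 cover
#: the weight-maintenance year.
WEEKS: tuple[int, ...] = (-8, 0, 4, 13, 26, 39, 52)

#: Weight-maintenance weeks used for longitudinal variability statistics.
MAINTENANCE_WEEKS: tuple[int, ...] = (4, 13, 26, 39, 52)

#: Maximum technical replicates per plasma sample (quadruplicate design).
MAX_REPLICATES: int = 4

#: Reserved flag names understood by the annotation reader.
RESERVED_FLAGS: tuple[str, ...] = (
    "erythrocyte_marker",
    "fibrinogen",
    "immunoglobulin",
)

SAMPLE_COLUMNS: tuple[str, ...] = ("individual_id", "week", "replicate")


class PlasmaProfilerError(Exception):
    """Base class for all package errors."""


class FormatError(PlasmaProfilerError):
    """A file does not conform to the expected dialect."""


class IntegrityError(PlasmaProfilerError):
    """Structurally valid input violates a cross-record invariant."""


class ValidationError(PlasmaProfilerError):
    """A configuration or argument value is out of its allowed domain."""


class NotEvaluableError(PlasmaProfilerError):
    """A statistic cannot be computed for this input (too few data etc.)."""


@dataclass(frozen=True)
class SampleKey:
    """Identity of one MS run: who, when, and which technical replicate."""

    individual_id: str
    week: int
    replicate: int
    run_label: str

    def __post_init__(self) -> None:
        if self.week not in WEEKS:
            raise ValidationError(
                f"week {self.week} is not on the sampling schedule {WEEKS}"
            )
        if not 1 <= self.replicate <= MAX_REPLICATES:
            raise ValidationError(
                f"replicate {self.replicate} outside 1..{MAX_REPLICATES}"
            )


@dataclass(frozen=True)
class ProteinId:
    """Protein-group identity with contaminant / decoy status."""

    accession: str
    gene_symbol: str
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError(f"empty gene symbol for accession {self.accession!r}")


def make_sample_table(samples: Iterable[SampleKey] | pd.DataFrame) -> pd.DataFrame:
    """Build and validate the run -> (individual, week, replicate) table.

    Returns a DataFrame indexed by ``run_label`` with columns
    ``individual_id``, ``week``, ``replicate``.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
        if df.index.name != "run_label":
            if "run_label" not in df.columns:
                raise FormatError("sample table lacks a 'run_label' column")
            df = df.set_index("run_label")
        df = df[list(SAMPLE_COLUMNS)]
    else:
        keys = list(samples)
        df = pd.DataFrame(
            {
                "individual_id": [k.individual_id for k in keys],
                "week": [k.week for k in keys],
                "replicate": [k.replicate for k in keys],
            },
            index=pd.Index([k.run_label for k in keys], name="run_label"),
        )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate run labels: {dupes}")
    df["week"] = df["week"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    bad_weeks = sorted(set(df["week"]) - set(WEEKS))
    if bad_weeks:
        raise IntegrityError(f"weeks {bad_weeks} are not on the schedule {WEEKS}")
    if (df["replicate"] < 1).any() or (df["replicate"] > MAX_REPLICATES).any():
        raise IntegrityError(f"replicate numbers must lie in 1..{MAX_REPLICATES}")
    counts = df.groupby(["individual_id", "week"]).size()
    if (counts > MAX_REPLICATES).any():
        where = counts[counts > MAX_REPLICATES].index.tolist()
        raise IntegrityError(f"more than {MAX_REPLICATES} replicates for {where}")
    return df


@dataclass
class IntensityMatrix:
    """Proteins x runs LFQ intensity matrix with explicit missing values.

    Parameters
    ----------
    values
        Linear-scale intensities, index = accession, columns = run labels.
        NaN encodes "not quantified"; stored values must be > 0.
    proteins
        Per-accession metadata (``gene_symbol``, ``is_contaminant``,
        ``is_reverse``), index aligned with ``values``.
    samples
        Run metadata as produced by :func:`make_sample_table`.
    """

    values: pd.DataFrame
    proteins: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = make_sample_table(self.samples)
        if not self.values.index.equals(self.proteins.index):
            raise IntegrityError("values and proteins indexes disagree")
        if list(self.values.columns) != list(self.samples.index):
            raise IntegrityError("values columns and sample run labels disagree")
        if self.values.index.has_duplicates:
            raise IntegrityError("duplicate protein accessions")
        self.values.index.name = "accession"
        self.values.columns.name = "run_label"
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise IntegrityError("intensities must be missing or > 0")
        for col in ("gene_symbol", "is_contaminant", "is_reverse"):
            if col not in self.proteins.columns:
                raise FormatError(f"protein table lacks column {col!r}")
        if (self.proteins["gene_symbol"].astype(str) == "").any():
            raise IntegrityError("empty gene symbol in protein table")

    # -- convenience ------------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    def log2(self) -> pd.DataFrame:
        """Log2-transformed intensities (missing stays NaN)."""
        return np.log2(self.values)

    def gene_map(self) -> dict[str, list[str]]:
        """Mapping gene symbol -> list of accessions carrying it."""
        out: dict[str, list[str]] = {}
        for acc, gene in self.proteins["gene_symbol"].items():
            out.setdefault(str(gene), []).append(acc)
        return out

    def accessions_for(self, genes: Iterable[str]) -> list[str]:
        gm = self.gene_map()
        return [acc for g in genes for acc in gm.get(g, [])]

    def subset_proteins(self, accessions: Sequence[str]) -> "IntensityMatrix":
        accs = list(accessions)
        return IntensityMatrix(
            values=self.values.loc[accs].copy(),
            proteins=self.proteins.loc[accs].copy(),
            samples=self.samples.copy(),
        )

    def subset_runs(self, run_labels: Sequence[str]) -> "IntensityMatrix":
        labels = list(run_labels)
        return IntensityMatrix(
            values=self.values[labels].copy(),
            proteins=self.proteins.copy(),
            samples=self.samples.loc[labels].copy(),
        )


@dataclass
class ClinicalTable:
    """Clinical covariates per (individual, week).

    ``data`` is indexed by a (individual_id, week) MultiIndex; columns are
    covariates (weight kg, BMI kg/m2, HDL, LDL, cholesterol, triglycerides,
    glucose, leptin, HOMA-IR, ...).  Unknown variables are preserved under
    their given names.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.nlevels != 2:
            raise FormatError("clinical table must be keyed by (individual_id, week)")
        self.data.index = self.data.index.set_names(["individual_id", "week"])
        if self.data.index.has_duplicates:
            raise IntegrityError("duplicate (individual, week) rows in clinical table")
        if "BMI" in self.data.columns:
            bmi = self.data["BMI"].dropna()
            if (bmi <= 0).any():
                raise IntegrityError("BMI must be > 0 where present")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def series(self, variable: str) -> pd.Series:
        """One covariate as a Series over (individual, week)."""
        if variable not in self.data.columns:
            raise ValidationError(f"unknown clinical variable {variable!r}")
        return self.data[variable].dropna()


def _as_termset(value) -> frozenset[str]:
    if isinstance(value, frozenset):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    if isinstance(value, str):
        return frozenset(t.strip() for t in value.split(";") if t.strip())
    return frozenset(str(t).strip() for t in value if str(t).strip())


@dataclass
class AnnotationTable:
    """Per-gene keyword / GO-term sets and QC marker flags.

    ``data`` is indexed by gene symbol with columns ``keywords``, ``gocc``,
    ``gobp`` (frozensets of term strings, case preserved) and boolean flags
    ``erythrocyte_marker``, ``fibrinogen``, ``immunoglobulin``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        df.index.name = "gene_symbol"
        if (df.index == "").any():
            raise FormatError("empty gene symbol in annotation table")
        if df.index.has_duplicates:
            raise IntegrityError("duplicate gene symbols in annotation table")
        for col in ("keywords", "gocc", "gobp"):
            df[col] = df[col].map(_as_termset) if col in df else [frozenset()] * len(df)
        for flag in RESERVED_FLAGS:
            df[flag] = df[flag].astype(bool) if flag in df else False
        self.data = df[["keywords", "gocc", "gobp", *RESERVED_FLAGS]]

    def genes_with_flag(self, flag: str) -> list[str]:
        if flag not in RESERVED_FLAGS:
            raise ValidationError(f"unknown flag {flag!r}")
        return list(self.data.index[self.data[flag]])

    def genes_with_any_keyword(self, keywords: Iterable[str]) -> list[str]:
        """Genes whose keyword set contains any of ``keywords`` (case-insensitive)."""
        wanted = {k.lower() for k in keywords}
        hits = []
        for gene, kws in self.data["keywords"].items():
            if any(k.lower() in wanted for k in kws):
                hits.append(gene)
        return hits

    def terms(self, column: str) -> set[str]:
        """All distinct terms appearing in a term-set column."""
        if column not in ("keywords", "gocc", "gobp"):
            raise ValidationError(f"no term column {column!r}")
        out: set[str] = set()
        for s in self.data[column]:
            out |= s
        return out

    def genes_with_term(self, column: str, term: str) -> list[str]:
        return [g for g, s in self.data[column].items() if term in s]


@dataclass
class AggregatedMatrix:
    """Replicate-aggregated log2 intensities per (protein, individual, week).

    ``values`` is indexed by accession with a (individual_id, week)
    MultiIndex on the columns; ``counts`` records how many observed
    replicates each cell derives from (0 == missing cell).
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    proteins: pd.DataFrame
    method: str = "median"

    def __post_init__(self) -> None:
        if self.values.columns.nlevels != 2:
            raise IntegrityError("aggregated columns must be (individual_id, week)")
        self.values.columns = self.values.columns.set_names(["individual_id", "week"])
        self.counts.columns = self.counts.columns.set_names(["individual_id", "week"])
        if self.values.shape != self.counts.shape:
            raise IntegrityError("values and counts shapes disagree")
        observed = self.values.notna().to_numpy()
        counts = self.counts.to_numpy()
        if np.any(observed & (counts < 1)) or np.any(~observed & (counts != 0)):
            raise IntegrityError("replicate counts inconsistent with missingness")

    @property
    def weeks(self) -> list[int]:
        return sorted(set(self.values.columns.get_level_values("week")))

    @property
    def individuals(self) -> list[str]:
        return sorted(set(self.values.columns.get_level_values("individual_id")))

    def week_slice(self, week: int) -> pd.DataFrame:
        """Proteins x individuals values at one week."""
        sub = self.values.xs(week, axis=1, level="week")
        return sub

    def individual_slice(self, individual_id: str) -> pd.DataFrame:
        """Proteins x weeks values for one individual."""
        return self.values.xs(individual_id, axis=1, level="individual_id")

    def linear(self) -> pd.DataFrame:
        """Back-transformed linear-scale intensities."""
        return 2.0 ** self.values

    def gene_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for acc, gene in self.proteins["gene_symbol"].items():
            out.setdefault(str(gene), []).append(acc)
        return out

    def accessions_for(self, genes: Iterable[str]) -> list[str]:
        gm = self.gene_map()
        return [acc for g in genes for acc in gm.get(g, [])]
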