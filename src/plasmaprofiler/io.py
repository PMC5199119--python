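"""Readers and writers for the tabular dialects used by the pipeline.

Two intensity dialects are supported:

``proteingroups``
    A MaxQuant ``proteinGroups.txt``-style TSV with identifier columns
    (``Protein IDs``, ``Gene names``), one ``LFQ intensity <run>`` column
    per run and ``+``-marked ``Reverse`` / ``Potential contaminant``
    columns.  LFQ zeros are mapped to missing.
``plain``
    A minimal TSV with ``accession``, ``gene_symbol`` and one column per
    run.  Zeros are likewise treated as not-quantified.

Run labels are resolved into :class:`~plasmaprofiler.model.SampleKey`
entries either through a sidecar sample-annotation TSV
(``run_label  individual_id  week  replicate``) or through a regular
expression with named groups ``individual``, ``week`` and ``replicate``.
All files are UTF-8 with "." as the decimal separator.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    RESERVED_FLAGS,
    AnnotationTable,
    ClinicalTable,
    FormatError,
    IntegrityError,
    IntensityMatrix,
    make_sample_table,
)

LFQ_PREFIX = "LFQ intensity "
_PG_ID_COLUMNS = ("Protein IDs", "Gene names")


def _check_duplicate_header(path: Path, sep: str) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise IntegrityError(f"duplicate column {col!r} in {path}")
        seen.add(col)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sidecar run-annotation TSV into a validated sample table."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "run_label": str})
    missing = {"run_label", "individual_id", "week", "replicate"} - set(df.columns)
    if missing:
        raise FormatError(f"sample annotation lacks column(s) {sorted(missing)}")
    return make_sample_table(df)


def _samples_from_pattern(run_labels: Iterable[str], pattern: str) -> pd.DataFrame:
    rx = re.compile(pattern)
    records = []
    for label in run_labels:
        m = rx.match(label)
        if m is None:
            raise FormatError(f"run label {label!r} does not match pattern {pattern!r}")
        records.append(
            {
                "run_label": label,
                "individual_id": m.group("individual"),
                "week": int(m.group("week").replace("m", "-")),
                "replicate": int(m.group("replicate")),
            }
        )
    return make_sample_table(pd.DataFrame(records))


def read_intensity_matrix(
    path: str | Path,
    dialect: str = "proteingroups",
    samples: str | Path | pd.DataFrame | None = None,
    label_pattern: str | None = None,
) -> IntensityMatrix:
    """Load an LFQ intensity table.

    Parameters
    ----------
    path
        The intensity TSV.
    dialect
        ``"proteingroups"`` or ``"plain"`` (see module docstring).
    samples
        Sidecar sample-annotation TSV path or pre-built sample DataFrame.
    label_pattern
        Alternative to ``samples``: regex with named groups ``individual``,
        ``week``, ``replicate`` applied to each run label.
    """
    path = Path(path)
    if dialect not in ("proteingroups", "plain"):
        raise FormatError(f"unknown dialect {dialect!r}")
    _check_duplicate_header(path, "\t")
    df = pd.read_csv(path, sep="\t")

    if dialect == "proteingroups":
        for col in _PG_ID_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
        if not lfq_cols:
            raise FormatError(f"no {LFQ_PREFIX!r} columns found")
        accession = df["Protein IDs"].astype(str).str.split(";").str[0]
        gene = df["Gene names"].astype(str).str.split(";").str[0]
        is_rev = accession.str.startswith("REV__")
        is_con = accession.str.startswith("CON__")
        if "Reverse" in df.columns:
            is_rev |= df["Reverse"].astype(str).str.strip() == "+"
        if "Potential contaminant" in df.columns:
            is_con |= df["Potential contaminant"].astype(str).str.strip() == "+"
        values = df[lfq_cols].astype(float)
        values.columns = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    else:
        if "accession" not in df.columns:
            raise FormatError("missing required column 'accession'")
        accession = df["accession"].astype(str)
        gene = (
            df["gene_symbol"].astype(str)
            if "gene_symbol" in df.columns
            else accession
        )
        run_cols = [c for c in df.columns if c not in ("accession", "gene_symbol")]
        if not run_cols:
            raise FormatError("no run columns found in plain matrix")
        values = df[run_cols].astype(float)
        is_rev = pd.Series(False, index=df.index)
        is_con = pd.Series(False, index=df.index)

    values = values.mask(values == 0.0)  # LFQ zero == not quantified
    if np.any(values.to_numpy() < 0):
        raise IntegrityError("negative intensity encountered")
    values.index = pd.Index(accession, name="accession")
    proteins = pd.DataFrame(
        {
            "gene_symbol": gene.values,
            "is_contaminant": is_con.values,
            "is_reverse": is_rev.values,
        },
        index=values.index,
    )

    if samples is None and label_pattern is None:
        raise FormatError("either a sample annotation or a label pattern is required")
    if samples is not None:
        table = samples if isinstance(samples, pd.DataFrame) else read_sample_table(samples)
        missing_runs = [c for c in values.columns if c not in table.index]
        if missing_runs:
            raise IntegrityError(f"runs without sample annotation: {missing_runs}")
        table = table.loc[list(values.columns)]
    else:
        table = _samples_from_pattern(values.columns, label_pattern)

    return IntensityMatrix(values=values, proteins=proteins, samples=table)


def write_intensity_matrix(
    matrix: IntensityMatrix, path: str | Path, dialect: str = "plain"
) -> None:
    """Write the matrix back out; missing cells become LFQ zeros."""
    path = Path(path)
    filled = matrix.values.fillna(0.0)
    if dialect == "plain":
        out = filled.copy()
        out.insert(0, "gene_symbol", matrix.proteins["gene_symbol"])
        out.insert(0, "accession", matrix.values.index)
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "proteingroups":
        out = pd.DataFrame(
            {
                "Protein IDs": matrix.values.index,
                "Gene names": matrix.proteins["gene_symbol"].values,
                "Reverse": np.where(matrix.proteins["is_reverse"], "+", ""),
                "Potential contaminant": np.where(
                    matrix.proteins["is_contaminant"], "+", ""
                ),
            }
        )
        for run in filled.columns:
            out[LFQ_PREFIX + run] = filled[run].values
        out.to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False)


# -- clinical ------------------------------------------------------------


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical covariate CSV (long or wide layout)."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    if {"variable", "value"} <= set(df.columns):
        required = {"individual_id", "week"}
        if not required <= set(df.columns):
            raise FormatError("long clinical table needs individual_id and week")
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = values.isna() & df["value"].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric clinical value at row {row}")
        key = df[["individual_id", "week", "variable"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise IntegrityError(f"duplicate clinical record {dup}")
        wide = df.assign(value=values).pivot(
            index=["individual_id", "week"], columns="variable", values="value"
        )
        wide.columns.name = None
    else:
        if not {"individual_id", "week"} <= set(df.columns):
            raise FormatError("wide clinical table needs individual_id and week")
        if df[["individual_id", "week"]].duplicated().any():
            raise IntegrityError("duplicate (individual, week) clinical rows")
        wide = df.set_index(["individual_id", "week"])
        for col in wide.columns:
            coerced = pd.to_numeric(wide[col], errors="coerce")
            bad = coerced.isna() & wide[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(f"non-numeric value in {col!r} at row {row}")
            wide[col] = coerced
    return ClinicalTable(data=wide.sort_index())


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    """Write in long layout (individual_id, week, variable, value)."""
    long = (
        table.data.stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_2": "variable"})
    )
    long.to_csv(path, index=False)


# -- annotations ---------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a per-gene annotation TSV with semicolon-separated term lists."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "gene_symbol" not in df.columns:
        raise FormatError("missing required column 'gene_symbol'")
    if (df["gene_symbol"].str.strip() == "").any():
        row = int(np.flatnonzero((df["gene_symbol"].str.strip() == "").to_numpy())[0])
        raise FormatError(f"empty gene symbol at row {row}")
    out = pd.DataFrame(index=pd.Index(df["gene_symbol"].str.strip(), name="gene_symbol"))
    for col in ("keywords", "gocc", "gobp"):
        out[col] = (
            df[col].values if col in df.columns else ""
        )
    flags = df["flags"] if "flags" in df.columns else pd.Series("", index=df.index)
    flagsets = flags.map(lambda s: {t.strip() for t in s.split(";") if t.strip()})
    for flag in RESERVED_FLAGS:
        out[flag] = [flag in s for s in flagsets]
    return AnnotationTable(data=out)


def write_annotations(annotations: AnnotationTable, path: str | Path) -> None:
    df = annotations.data
    out = pd.DataFrame(
        {
            "gene_symbol": df.index,
            "keywords": [";".join(sorted(s)) for s in df["keywords"]],
            "gocc": [";".join(sorted(s)) for s in df["gocc"]],
            "gobp": [";".join(sorted(s)) for s in df["gobp"]],
            "flags": [
                ";".join(f for f in RESERVED_FLAGS if df.loc[g, f]) for g in df.index
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)
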