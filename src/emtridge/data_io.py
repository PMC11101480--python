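"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain text: expression as TSV (first column gene
identifier, header row of sample identifiers), phenotype and clinical tables
as CSV with header, gene-set libraries as GMT. Data files are written at
full float precision so write/read round-trips are lossless to 1e-12.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GeneSetLibrary, PhenotypeTable
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _check_path(path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise OSError(f"no such file: {p}")
    return p


def read_expression(path, cohort: str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV into an :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (the usual signature-transfer convention); the number of
    collapsed rows is logged.
    """
    p = _check_path(path)
    try:
        df = pd.read_csv(p, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{p}: empty expression file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{p}: malformed TSV (ragged rows?): {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{p}: expression table has no data (shape {df.shape})")
    bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(bad):
        col = bad[0]
        nonnum = pd.to_numeric(df[col], errors="coerce")
        row = df.index[int(np.argmax(nonnum.isna().to_numpy()))]
        raise ParseError(f"{p}: non-numeric value at gene {row!r}, sample {col!r}")
    if df.isna().any().any():
        raise ParseError(f"{p}: missing values in expression body")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        df = (
            df.assign(_mean=df.mean(axis=1))
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        df = df.sort_index()
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept highest mean)", p, n_dup
        )
    return ExpressionMatrix(df.astype(float), cohort)


def write_expression(matrix: ExpressionMatrix, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(p, sep="\t", float_format=_FLOAT_FMT, index_label="gene_id")
    return p


def read_phenotypes(path) -> PhenotypeTable:
    """Read a cell-line-by-phenotype CSV (first column = cell line id)."""
    p = _check_path(path)
    try:
        df = pd.read_csv(p, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{p}: empty phenotype file") from exc
    if df.isna().any().any():
        raise ParseError(f"{p}: missing phenotype values")
    return PhenotypeTable(df.astype(float))


def write_phenotypes(table: PhenotypeTable, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(p, float_format=_FLOAT_FMT, index_label="cellline_id")
    return p


def read_clinical(path) -> ClinicalTable:
    """Read the per-patient clinical CSV; missing cells are preserved."""
    p = _check_path(path)
    try:
        df = pd.read_csv(p, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{p}: empty clinical file") from exc
    out = pd.DataFrame(index=df.index)
    out["mandard"] = pd.array(df.get("mandard"), dtype="Int64")
    out["recurrence"] = pd.array(df.get("recurrence"), dtype="boolean")
    out["os_time"] = pd.to_numeric(df.get("os_time"), errors="raise")
    out["os_event"] = pd.array(df.get("os_event"), dtype="boolean")
    return ClinicalTable(out)


def write_clinical(table: ClinicalTable, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(p, float_format=_FLOAT_FMT, index_label="patient_id")
    return p


def read_gmt(path) -> GeneSetLibrary:
    """Parse a GMT gene-set file (set name, description, members; tabs).

    Empty lines are skipped; duplicate members within a line are stored once;
    the description field is ignored. Membership is independent of line
    order within the file.
    """
    p = _check_path(path)
    sets: dict[str, tuple[str, ...]] = {}
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise ParseError(
                    f"{p}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(tokens)}"
                )
            name = tokens[0]
            if name in sets:
                raise ParseError(f"{p}: line {lineno}: duplicate set name {name!r}")
            members: dict[str, None] = {}
            for g in tokens[2:]:
                if g:
                    members.setdefault(g)
            if not members:
                raise ParseError(f"{p}: line {lineno}: set {name!r} has no members")
            sets[name] = tuple(members)
    return GeneSetLibrary(sets)


def write_gmt(library: GeneSetLibrary, path, description: str = "na") -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        for name, members in library.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
    return p


def read_series_csv(path, value_column: str) -> pd.Series:
    """Read a two-column CSV (id, value) as a float Series."""
    p = _check_path(path)
    df = pd.read_csv(p, index_col=0)
    if value_column not in df.columns:
        raise ParseError(f"{p}: expected column {value_column!r}")
    return df[value_column].astype(float)


def write_series_csv(series: pd.Series, path, id_label: str, value_column: str) -> Path:
    p = Path(path)
    if str(path) == "":
        raise OSError("empty output path")
    p.parent.mkdir(parents=True, exist_ok=True)
    series.rename(value_column).to_csv(
        p, float_format=_FLOAT_FMT, index_label=id_label
    )
    return p


def ensure_writable_dir(directory) -> Path:
    d = Path(directory)
    if str(directory) == "":
        raise OSError("empty directory name")
    d.mkdir(parents=True, exist_ok=True)
    if not os.access(d, os.W_OK):
        raise OSError(f"directory not writable: {d}")
    return d
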