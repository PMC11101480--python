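"""In-memory containers for the pipeline's data.

All tabular data is held in pandas objects; these thin wrappers pin down
orientation (genes x samples), enforce the structural invariants once at
construction, and carry the metadata (cohort label, phenotype names) that
plain DataFrames would lose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

COHORTS = ("cell_line", "tumor")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log-scale expression values.

    Parameters
    ----------
    values : pd.DataFrame
        Rows indexed by gene identifier, columns by sample identifier.
    cohort : str
        Either ``"cell_line"`` or ``"tumor"``.
    """

    values: pd.DataFrame
    cohort: str

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"cohort must be one of {COHORTS}, got {self.cohort!r}"
            )
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup}")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} requested genes absent from matrix, "
                f"e.g. {missing[:5]}"
            )
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.cohort)


@dataclass
class PhenotypeTable:
    """Cell line x phenotype table of scaled-comparable phenotype values."""

    values: pd.DataFrame  # rows: cell lines, columns: phenotype names

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValidationError("duplicate cell-line identifiers")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate phenotype names")

    @property
    def cellline_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def phenotype_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-patient clinical outcomes.

    Columns: ``mandard`` (ordinal 1-4, nullable), ``recurrence`` (boolean,
    nullable), ``os_time`` (months, nullable), ``os_event`` (boolean,
    nullable). Missing values are allowed and are excluded pairwise by each
    association, since for some samples clinical variables are unavailable.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mandard", "recurrence", "os_time", "os_event"}
        missing = required - set(self.values.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        if not self.values.index.is_unique:
            raise ValidationError("duplicate patient identifiers")
        m = self.values["mandard"].dropna()
        if not m.isin([1, 2, 3, 4]).all():
            raise ValidationError("mandard categories must be in {1,2,3,4}")
        t, e = self.values["os_time"], self.values["os_event"]
        if (t.dropna() < 0).any():
            raise ValidationError("os_time must be nonnegative")
        if (e.notna() & t.isna()).any():
            raise ValidationError("os_time required wherever os_event is present")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class GeneSetLibrary:
    """Named gene sets (transcription factor -> putative target genes)."""

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                # deduplicate silently-deterministically, preserving order
                seen: dict[str, None] = {}
                for g in members:
                    seen.setdefault(g)
                self.sets[name] = tuple(seen)

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]
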