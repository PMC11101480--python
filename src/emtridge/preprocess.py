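"""Normalisation and the two-stage gene filter applied before training.

The filter chain: (1) restrict to genes present in both cohorts, keep the
intersection of each cohort's top-fraction (default 33%) by mean expression;
(2) from those candidates keep the top-n (default 5000) by variance computed
on the cell-line (training) matrix. Both stages are deterministic: cutoffs
use floor(), ties at any boundary break by gene identifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    expressed_fraction: float = 0.33
    n_variable: int = 5000

    def __post_init__(self) -> None:
        if not (0 < self.expressed_fraction <= 1):
            raise ValidationError(
                f"expressed_fraction must be in (0, 1], got {self.expressed_fraction}"
            )
        if self.n_variable < 1:
            raise ValidationError(f"n_variable must be >= 1, got {self.n_variable}")


@dataclass(frozen=True)
class ScaleParams:
    """Stored (mean, sd) of a training vector, reusable on new data."""

    mean: float
    sd: float

    def apply(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


def normalize_log2(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalisation followed by log2(x + 1).

    Each sample (column) is scaled so all columns share the mean column sum,
    then log2(x+1)-transformed. This is a simple stand-in for a
    variance-stabilising transform and is logged as such; pre-normalised
    log-scale input should bypass this step entirely.
    """
    vals = raw.values
    arr = vals.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("normalize_log2 expects nonnegative values")
    colsums = arr.sum(axis=0)
    if (colsums == 0).any():
        bad = vals.columns[colsums == 0][:5].tolist()
        raise ValidationError(f"all-zero samples: {bad}")
    target = colsums.mean()
    scaled = arr * (target / colsums)
    logger.info(
        "normalize_log2: library-size scaling + log2(x+1) applied "
        "(simple stand-in for a variance-stabilising transform)"
    )
    out = pd.DataFrame(np.log2(scaled + 1.0), index=vals.index, columns=vals.columns)
    return ExpressionMatrix(out, raw.cohort)


def _top_by_mean(matrix: ExpressionMatrix, genes: list[str], k: int) -> set[str]:
    means = matrix.values.loc[genes].mean(axis=1)
    order = sorted(genes, key=lambda g: (-means[g], g))
    return set(order[:k])


def expression_filter(
    celllines: ExpressionMatrix,
    tumors: ExpressionMatrix,
    params: FilterParams = FilterParams(),
) -> set[str]:
    """Genes in the top ``expressed_fraction`` by mean expression in *both*
    cohorts, over the shared gene universe.

    The per-cohort cutoff count is ``floor(fraction * n_shared)``; boundary
    ties break lexicographically by gene id.
    """
    shared = sorted(set(celllines.gene_ids) & set(tumors.gene_ids))
    if not shared:
        raise ValidationError("no shared gene identifiers between cohorts")
    k = math.floor(params.expressed_fraction * len(shared))
    top_cl = _top_by_mean(celllines, shared, k)
    top_tu = _top_by_mean(tumors, shared, k)
    retained = top_cl & top_tu
    logger.info(
        "expression_filter: %d shared genes, cutoff %d per cohort, %d retained",
        len(shared), k, len(retained),
    )
    return retained


def variance_filter(
    celllines: ExpressionMatrix,
    candidate_genes,
    params: FilterParams = FilterParams(),
) -> list[str]:
    """Top ``n_variable`` candidates by variance on the cell-line matrix.

    Returned in decreasing-variance order (ties by gene id). If fewer
    candidates than requested, all are retained with a warning.
    """
    candidates = sorted(set(candidate_genes))
    if not candidates:
        raise ValidationError("empty candidate gene set")
    missing = set(candidates) - set(celllines.gene_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} candidates absent from cell-line matrix"
        )
    var = celllines.values.loc[candidates].var(axis=1, ddof=1)
    order = sorted(candidates, key=lambda g: (-var[g], g))
    if len(order) < params.n_variable:
        logger.warning(
            "variance_filter: only %d candidates for n_variable=%d; keeping all",
            len(order), params.n_variable,
        )
        return order
    return order[: params.n_variable]


def scale_center(values) -> tuple[np.ndarray, ScaleParams]:
    """Center to mean 0 and scale to unit sd (denominator n-1).

    Returns the transformed vector and the transform parameters for reuse on
    new data. A constant vector has no defined scale and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("scale_center needs a 1-d vector of length >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("cannot scale a constant vector")
    params = ScaleParams(mean=mean, sd=sd)
    return params.apply(x), params
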