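"""Transcription-factor-target over-representation on the pooled top genes.

The top positive-coefficient genes of the selected models are pooled and
tested against each set of a TF-target library with the one-sided
hypergeometric (Fisher exact) test, conditioning on the post-filter gene
universe as background. P-values are corrected across sets with
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetLibrary
from .exceptions import ValidationError
from .plasticity_ridge import RidgeModel, top_coefficient_genes

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    query_size: int
    set_size: int
    background_size: int
    odds_ratio: float
    p_value: float
    q_value: float


def pool_top_genes(models: list[RidgeModel], k: int = 25) -> list[str]:
    """Deduplicated union of each model's top-k positive-coefficient genes.

    Returned sorted by gene id for determinism. Three disjoint top-25 lists
    pool to 75 genes; identical lists pool to 25.
    """
    if not models:
        raise ValidationError("empty model set")
    pooled: set[str] = set()
    for m in models:
        pos, _ = top_coefficient_genes(m, k)
        pooled.update(pos)
    return sorted(pooled)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-d vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_enrichment(
    query, library: GeneSetLibrary, background
) -> list[EnrichmentResult]:
    """One-sided over-representation test of ``query`` in each library set.

    Per set: members are intersected with the background; the upper-tail
    hypergeometric p is P(overlap >= observed); the odds ratio comes from
    the 2x2 table with a Haldane 0.5 correction when any cell is zero. Sets
    with zero background overlap are skipped and logged. Results are sorted
    by (q, p, name).
    """
    bg = set(background)
    q_set = set(query)
    if not q_set <= bg:
        extra = sorted(q_set - bg)[:5]
        raise ValidationError(f"query genes outside background, e.g. {extra}")
    N = len(bg)
    n = len(q_set)
    rows: list[EnrichmentResult] = []
    for name in library.set_names:
        members = set(library[name]) & bg
        K = len(members)
        if K == 0:
            logger.info("set %s has no background overlap; skipped", name)
            continue
        a = len(q_set & members)
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        p = min(p, 1.0)
        b = n - a
        c = K - a
        d = N - K - n + a
        if min(a, b, c, d) == 0:
            a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a_, b_, c_, d_ = a, b, c, d
        odds = (a_ * d_) / (b_ * c_)
        rows.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=a,
                query_size=n,
                set_size=K,
                background_size=N,
                odds_ratio=odds,
                p_value=p,
                q_value=float("nan"),
            )
        )
    if not rows:
        return []
    q = bh_fdr([r.p_value for r in rows])
    for r, qv in zip(rows, q):
        r.q_value = float(qv)
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return rows


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view with volcano-style columns (-log10 p, log2 odds)."""
    df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        return df
    df["neg_log10_p"] = -np.log10(df["p_value"])
    df["log2_odds_ratio"] = np.log2(df["odds_ratio"])
    return df


def write_results(results: list[EnrichmentResult], path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(p, sep="\t", index=False, float_format="%.6g")
    return p
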