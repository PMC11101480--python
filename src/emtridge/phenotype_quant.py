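"""Quantification of the six in-vitro phenotypes that anchor the models.

Five phenotypes are flow-cytometry marker inductions: the geometric-mean
fluorescence of a marker is background-corrected against its isotype control
(``delta_gmfi``), and the log2 ratio of the treated over the untreated
corrected signal is the induction score entered into the phenotype table.
The sixth phenotype is a morphology-onset rank assigned by several blinded
observers and averaged; inter-observer agreement is summarised by Cohen's
kappa.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError, ValidationError

#: floor for the background-corrected signal, as a fraction of the isotype
#: control; keeps the downstream log2 defined when marker == background.
EPSILON_FRACTION = 1e-6


def delta_gmfi(gmfi: float, isotype_gmfi: float) -> float:
    """Background-corrected geometric-mean fluorescence (gMFI - isotype).

    The difference is floored at ``EPSILON_FRACTION * isotype_gmfi`` so that
    signal indistinguishable from the isotype control yields a small positive
    value instead of zero or a negative number.
    """
    if gmfi <= 0 or isotype_gmfi <= 0:
        raise ValidationError(
            f"gMFI values must be positive, got gmfi={gmfi}, isotype={isotype_gmfi}"
        )
    return max(gmfi - isotype_gmfi, EPSILON_FRACTION * isotype_gmfi)


def induction_score(delta_crt: float, delta_untreated: float) -> float:
    """log2 fold induction of a marker under chemoradiation.

    Both inputs are post-floor ``delta_gmfi`` values, hence positive.
    Antisymmetric under swapping treated/untreated.
    """
    if delta_crt <= 0 or delta_untreated <= 0:
        raise ValidationError("delta gMFI inputs must be positive (post-floor)")
    return math.log2(delta_crt / delta_untreated)


def consensus_morphology(scores: pd.DataFrame) -> pd.Series:
    """Average morphology-onset ranks over observers.

    Parameters
    ----------
    scores : DataFrame
        Tidy table with columns ``cellline_id``, ``observer_id``,
        ``onset_rank``. Within one observer the ranks must be a permutation
        of 1..n (midranks allowed for ties). Lower rank = faster onset of
        mesenchymal morphology.

    Returns
    -------
    Series indexed by cell line, the mean rank over observers. Invariant to
    observer ordering.
    """
    required = {"cellline_id", "observer_id", "onset_rank"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"morphology table needs columns {sorted(required)}")
    observers = scores["observer_id"].unique()
    if len(observers) < 2:
        raise ValidationError("need ratings from at least 2 observers")
    sets = {
        obs: frozenset(scores.loc[scores["observer_id"] == obs, "cellline_id"])
        for obs in observers
    }
    reference = next(iter(sets.values()))
    if any(s != reference for s in sets.values()):
        raise ValidationError("observers rated different cell-line sets")
    for obs in observers:
        sub = scores[scores["observer_id"] == obs]
        if sub["cellline_id"].duplicated().any():
            raise ValidationError(f"observer {obs!r} rated a cell line twice")
        ranks = np.sort(sub["onset_rank"].to_numpy(dtype=float))
        n = len(ranks)
        if not math.isclose(ranks.sum(), n * (n + 1) / 2, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"observer {obs!r}: ranks are not a (mid)rank permutation of 1..{n}"
            )
    return (
        scores.groupby("cellline_id")["onset_rank"].mean().rename("morphology")
    )


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa for two equal-length categorical rating vectors.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the product of marginals. When p_e == 1 (both raters
    constant with identical marginals) kappa is undefined and an
    :class:`UndefinedStatisticError` is raised.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("ratings must be equal-length non-empty vectors")
    n = len(a)
    categories = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for cat in categories:
        p_e += float(np.mean(a == cat)) * float(np.mean(b == cat))
    if math.isclose(p_e, 1.0, rel_tol=0, abs_tol=1e-12):
        raise UndefinedStatisticError(
            "kappa undefined: chance agreement is 1 (constant identical marginals)"
        )
    return (p_o - p_e) / (1.0 - p_e)


def pairwise_kappas(ratings: dict) -> tuple[dict[tuple[str, str], float], float]:
    """All pairwise Cohen's kappas for >=2 observers, plus their mean.

    Multi-observer agreement is summarised as the mean of pairwise kappas
    (Cohen's statistic is inherently pairwise).
    """
    names = sorted(ratings)
    if len(names) < 2:
        raise ValidationError("need at least 2 observers")
    out: dict[tuple[str, str], float] = {}
    for x, y in itertools.combinations(names, 2):
        out[(x, y)] = cohens_kappa(ratings[x], ratings[y])
    return out, float(np.mean(list(out.values())))
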