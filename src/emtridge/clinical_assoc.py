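"""Outcome statistics: group comparisons, dichotomization, survival.

These tests are implemented here rather than delegated, because their exact
small-sample behaviour (enumeration p-values, tie handling, continuity
corrections) is part of the pipeline's contract; established library
implementations serve as independent cross-checks in the test suite.

Exact-vs-approximate crossovers are explicit parameters, not magic numbers:
Mann-Whitney enumerates the U null distribution when the pooled sample is
small and untied; Spearman enumerates all rank permutations for n <= 8.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps  # distributions only (t, chi2, normal)

from .exceptions import ValidationError
from .tf_enrichment import bh_fdr

logger = logging.getLogger(__name__)

#: largest pooled sample for which the exact Mann-Whitney null is enumerated
MWU_EXACT_MAX_N = 12
#: largest n for which Spearman p is computed by full permutation enumeration
SPEARMAN_EXACT_MAX_N = 8

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value out of (0,1]: {self.p_value}")


@dataclass
class SurvivalCurve:
    event_times: np.ndarray  # distinct times with >= 1 event, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, float)
        if len(s) and (np.any(np.diff(s) > 1e-12) or s[0] > 1 + 1e-12 or s[-1] < -1e-12):
            raise ValidationError("survival curve must be nonincreasing in [0,1]")

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(
    a, b, alternative: str = "two-sided", exact_max_n: int = MWU_EXACT_MAX_N
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    The statistic is U of the first group. For pooled n <= ``exact_max_n``
    with no ties, the p-value is exact by enumerating all rank assignments;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    _check_alternative(alternative)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    has_ties = len(np.unique(pooled)) < len(pooled)
    n = na + nb
    if n <= exact_max_n and not has_ties:
        # enumerate which rank positions (1..n) fall in group a
        dist: dict[float, int] = {}
        allr = np.arange(1, n + 1)
        for combo in itertools.combinations(range(n), na):
            u = float(allr[list(combo)].sum() - na * (na + 1) / 2)
            dist[u] = dist.get(u, 0) + 1
        total = math.comb(n, na)
        ge = sum(c for u, c in dist.items() if u >= u_a) / total
        le = sum(c for u, c in dist.items() if u <= u_a) / total
        if alternative == "greater":
            p = ge
        elif alternative == "less":
            p = le
        else:
            p = min(1.0, 2.0 * min(ge, le))
        method = "mann-whitney-exact"
    else:
        mu = na * nb / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            # all observations identical: no evidence either way
            return TestResult(u_a, 1.0, "mann-whitney-normal", (na, nb))
        sd = math.sqrt(var)
        if alternative == "greater":
            z = (u_a - mu - 0.5) / sd
            p = float(_sps.norm.sf(z))
        elif alternative == "less":
            z = (u_a - mu + 0.5) / sd
            p = float(_sps.norm.cdf(z))
        else:
            z = (abs(u_a - mu) - 0.5) / sd
            p = float(min(1.0, 2.0 * _sps.norm.sf(z)))
        method = "mann-whitney-normal"
    return TestResult(u_a, max(p, np.finfo(float).tiny), method, (na, nb))


def welch_t(a, b, alternative: str = "two-sided") -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    _check_alternative(alternative)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValidationError("zero variance in both groups")
    sa = va / len(a)
    sb = vb / len(b)
    t_stat = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    if alternative == "greater":
        p = float(_sps.t.sf(t_stat, df))
    elif alternative == "less":
        p = float(_sps.t.cdf(t_stat, df))
    else:
        p = float(min(1.0, 2.0 * _sps.t.sf(abs(t_stat), df)))
    return TestResult(
        float(t_stat), max(p, np.finfo(float).tiny), "welch-t", (len(a), len(b))
    )


def spearman_rho(x, y) -> float:
    """Spearman rho: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = _midranks(x)
    ry = _midranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValidationError("constant vector: Spearman rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x, y, alternative: str = "two-sided", exact_max_n: int = SPEARMAN_EXACT_MAX_N
) -> TestResult:
    """Spearman rank correlation with exact permutation p for small n.

    For n <= ``exact_max_n`` the null distribution of rho is enumerated over
    all n! permutations of the (mid)ranks of ``y``; beyond that the usual
    t approximation with n-2 degrees of freedom is used.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("need n >= 4 for a meaningful Spearman test")
    rho = spearman_rho(x, y)
    if n <= exact_max_n:
        rx = _midranks(x)
        ry = _midranks(y)
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c))
        rhos = []
        for perm in itertools.permutations(ry):
            pr = np.asarray(perm)
            pr_c = pr - pr.mean()
            rhos.append(float(rx_c @ pr_c) / (denom * math.sqrt(float(pr_c @ pr_c))))
        rhos = np.asarray(rhos)
        eps = 1e-12
        if alternative == "greater":
            p = float(np.mean(rhos >= rho - eps))
        elif alternative == "less":
            p = float(np.mean(rhos <= rho + eps))
        else:
            p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
        method = "spearman-exact"
    else:
        r = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t_stat = r * math.sqrt((n - 2) / (1 - r * r))
        if alternative == "greater":
            p = float(_sps.t.sf(t_stat, n - 2))
        elif alternative == "less":
            p = float(_sps.t.cdf(t_stat, n - 2))
        else:
            p = float(min(1.0, 2.0 * _sps.t.sf(abs(t_stat), n - 2)))
        method = "spearman-t"
    return TestResult(rho, max(p, np.finfo(float).tiny), method, (n,))


def dichotomize_median(values) -> np.ndarray:
    """Split at the median: value > median -> "high", <= median -> "low".

    Ties at the median go to the low group (deterministic and conservative).
    A degenerate all-equal input yields all-low with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError("need >= 2 values to dichotomize")
    med = float(np.median(x))
    labels = np.where(x > med, "high", "low")
    if (labels == "low").all():
        logger.warning("degenerate median split: all values in the low group")
    return labels


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is 1/True for an observed event, 0/False for censoring.
    Censored-only data yields a flat curve at 1 (no event times).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) != len(e) or len(t) == 0:
        raise ValidationError("times and events must be equal-length, non-empty")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    out_t, out_s, out_r, out_d = [], [], [], []
    s = 1.0
    for ut in np.unique(t[e]):
        n_risk = int(np.sum(t >= ut))
        d = int(np.sum((t == ut) & e))
        s *= 1.0 - d / n_risk
        out_t.append(ut)
        out_s.append(s)
        out_r.append(n_risk)
        out_d.append(d)
    return SurvivalCurve(
        event_times=np.asarray(out_t),
        survival=np.asarray(out_s),
        at_risk=np.asarray(out_r, dtype=int),
        events=np.asarray(out_d, dtype=int),
    )


def logrank_test(times, events, groups) -> TestResult:
    """Two-group log-rank test.

    Chi-square statistic from observed-minus-expected events in group 1
    summed over distinct event times, with the hypergeometric variance at
    each time; p from chi-square with 1 df. Symmetric in the group labels.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if not (len(t) == len(e) == len(g)):
        raise ValidationError("times, events, groups must have equal length")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {len(labels)}")
    in1 = g == labels[0]
    if in1.all() or (~in1).all():
        raise ValidationError("each group must be non-empty")
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e]):
        at_risk = t >= ut
        nj = int(at_risk.sum())
        n1j = int((at_risk & in1).sum())
        dj = int(((t == ut) & e).sum())
        d1j = int(((t == ut) & e & in1).sum())
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var == 0:
        return TestResult(0.0, 1.0, "logrank", (int(in1.sum()), int((~in1).sum())))
    stat = o_minus_e**2 / var
    p = float(_sps.chi2.sf(stat, df=1))
    return TestResult(
        float(stat),
        max(p, np.finfo(float).tiny),
        "logrank",
        (int(in1.sum()), int((~in1).sum())),
    )


def mandard_association(
    scores, mandard_categories, correct: bool = False
) -> list[TestResult]:
    """Pairwise Mann-Whitney U tests of a score across Mandard categories.

    Missing categories are excluded pairwise. No multiplicity correction by
    default (per-pair reporting); ``correct=True`` applies BH across pairs.
    """
    s = np.asarray(scores, dtype=float)
    m = np.asarray(mandard_categories, dtype=float)
    if len(s) != len(m):
        raise ValidationError("scores and categories must have equal length")
    keep = ~np.isnan(m)
    s, m = s[keep], m[keep].astype(int)
    if not np.isin(m, [1, 2, 3, 4]).all():
        raise ValidationError("Mandard categories must be in {1,2,3,4}")
    cats = sorted(set(m.tolist()))
    if len(cats) < 2:
        raise ValidationError("need >= 2 populated Mandard categories")
    results = []
    for c1, c2 in itertools.combinations(cats, 2):
        res = mann_whitney_u(s[m == c1], s[m == c2], alternative="two-sided")
        res.label = f"mandard {c1} vs {c2}"
        results.append(res)
    if correct:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.p_value = float(qv)
            r.method += "+bh"
    return results
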