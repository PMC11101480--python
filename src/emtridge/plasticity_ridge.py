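"""Per-phenotype ridge models with leave-one-out penalty selection.

The central computation: an L2-penalised linear model is trained on the
standardized expression of the (replicate-averaged) training cell lines for
each phenotype, the penalty lambda is chosen by leave-one-out
cross-validation over a log-spaced grid, and the fitted coefficient vector
is then projected onto patient biopsies to produce per-sample plasticity
scores.

Numerics: the coefficient solve uses the dual (kernel) form
``beta = Xc^T (Xc Xc^T + lambda I)^{-1} yc`` whenever p > n, which is exact
for lambda > 0 and identical to the primal normal-equations solution. The
LOOCV error curve is computed from the single SVD of the centered training
matrix via the leverage identity ``e_loo_i = e_i / (1 - h_ii)`` with
``h_ii = 1/n + sum_k u_ik^2 s_k^2/(s_k^2 + lambda)`` — the exact hat
diagonal of the ridge smoother with an unpenalised intercept, so the curve
equals n explicit refits to machine precision.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PhenotypeTable
from .exceptions import CoverageError, ValidationError
from .preprocess import ScaleParams, scale_center

logger = logging.getLogger(__name__)

#: default penalty grid: 50 points log-spaced over [1e-3, 1e5]
DEFAULT_LAMBDA_GRID = np.logspace(-3, 5, 50)

_REPLICATE_SUFFIX = re.compile(r"[_\-]rep\d+$", flags=re.IGNORECASE)


@dataclass
class RidgeFit:
    """Low-level ridge solution on a numeric (samples x features) matrix."""

    coefficients: np.ndarray
    intercept: float  # mean of the uncentered response
    feature_means: np.ndarray  # column means used for centering

    def fitted(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.feature_means) @ self.coefficients + (
            self.intercept
        )


@dataclass
class RidgeModel:
    """A trained per-phenotype model plus everything needed to apply it."""

    phenotype_name: str
    gene_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    lam: float
    train_gene_means: np.ndarray
    train_gene_sds: np.ndarray
    cv_error_curve: list[tuple[float, float]]
    n_folds: int
    cv_predictions: dict[str, float] = field(default_factory=dict)
    y_scale: ScaleParams | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("coefficients", "train_gene_means", "train_gene_sds"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != number of genes")
        if self.lam <= 0:
            raise ValidationError("model lambda must be positive")
        errs = {lam: err for lam, err in self.cv_error_curve}
        if self.lam not in errs or errs[self.lam] > min(errs.values()) + 1e-12:
            raise ValidationError("lambda must attain the minimal CV error")

    def to_json(self, path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "phenotype_name": self.phenotype_name,
            "gene_ids": self.gene_ids,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "train_gene_means": self.train_gene_means.tolist(),
            "train_gene_sds": self.train_gene_sds.tolist(),
            "cv_error_curve": [[la, er] for la, er in self.cv_error_curve],
            "n_folds": self.n_folds,
            "cv_predictions": self.cv_predictions,
            "y_scale": (
                None
                if self.y_scale is None
                else {"mean": self.y_scale.mean, "sd": self.y_scale.sd}
            ),
        }
        p.write_text(json.dumps(payload, indent=1))
        return p

    @classmethod
    def from_json(cls, path) -> "RidgeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            phenotype_name=d["phenotype_name"],
            gene_ids=list(d["gene_ids"]),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            train_gene_means=np.asarray(d["train_gene_means"], float),
            train_gene_sds=np.asarray(d["train_gene_sds"], float),
            cv_error_curve=[(float(a), float(b)) for a, b in d["cv_error_curve"]],
            n_folds=int(d["n_folds"]),
            cv_predictions={k: float(v) for k, v in d["cv_predictions"].items()},
            y_scale=(
                None
                if d.get("y_scale") is None
                else ScaleParams(d["y_scale"]["mean"], d["y_scale"]["sd"])
            ),
        )


@dataclass
class PlasticityScores:
    sample_ids: list[str]
    scores: np.ndarray
    model_name: str

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.scores):
            raise ValidationError("one score per sample required")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.model_name)


def fit_ridge(X, y, lam: float) -> RidgeFit:
    """Solve the L2-penalised least-squares problem.

    Coefficients solve ``(Xc^T Xc + lam I) beta = Xc^T yc`` on centered
    data; the intercept is the mean of the uncentered response. For p > n
    the equivalent dual form is used (identical for lam > 0). ``lam = 0``
    with p >= n is rank-deficient and rejected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValidationError(
            f"dimension mismatch: X {X.shape}, y {y.shape}"
        )
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if lam < 0:
        raise ValidationError("lambda must be nonnegative")
    if lam == 0 and p >= n:
        raise ValidationError(
            f"lambda=0 with p={p} >= n={n}: ordinary least squares is rank-deficient"
        )
    xm = X.mean(axis=0)
    Xc = X - xm
    ym = float(y.mean())
    yc = y - ym
    if p <= n:
        gram = Xc.T @ Xc + lam * np.eye(p)
        try:
            beta = np.linalg.solve(gram, Xc.T @ yc)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"singular system at lambda={lam}") from exc
    else:
        kern = Xc @ Xc.T + lam * np.eye(n)
        alpha = np.linalg.solve(kern, yc)
        beta = Xc.T @ alpha
    return RidgeFit(coefficients=beta, intercept=ym, feature_means=xm)


def loocv_select_lambda(X, y, lambda_grid=None) -> tuple[float, list[tuple[float, float]]]:
    """Leave-one-out CV error over a penalty grid; returns the minimiser.

    The curve is computed from one SVD of the centered matrix via the exact
    leverage identity (see module docstring); ties in the minimal error are
    resolved toward the *larger* lambda (more regularisation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("dimension mismatch between X and y")
    n = X.shape[0]
    if n < 3:
        raise ValidationError(f"LOOCV needs at least 3 samples, got {n}")
    grid = np.asarray(
        DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float
    )
    if len(grid) < 2 or (grid <= 0).any():
        raise ValidationError("lambda grid must contain >= 2 positive values")
    grid = np.sort(grid)
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ yc
    u2 = U**2
    curve: list[tuple[float, float]] = []
    for lam in grid:
        shrink = s**2 / (s**2 + lam)
        resid = yc - U @ (shrink * uty)
        h = 1.0 / n + u2 @ shrink
        denom = 1.0 - h
        if np.any(denom <= 1e-12):
            mse = float("inf")  # interpolating fit; LOO error unbounded
        else:
            mse = float(np.mean((resid / denom) ** 2))
        curve.append((float(lam), mse))
    errors = np.array([e for _, e in curve])
    best = errors.min()
    # ties toward the larger lambda
    tied = np.nonzero(np.isclose(errors, best, rtol=1e-12, atol=0.0))[0]
    lam_opt = float(grid[tied[-1]])
    return lam_opt, curve


def loocv_predictions(X, y, lam: float) -> np.ndarray:
    """Leave-one-out predictions at a fixed lambda (same leverage identity)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    shrink = s**2 / (s**2 + lam)
    fitted = ym + U @ (shrink * (U.T @ yc))
    h = 1.0 / n + (U**2) @ shrink
    return y - (y - fitted) / (1.0 - h)


def _default_line_of(sample_id: str) -> str:
    return _REPLICATE_SUFFIX.sub("", sample_id)


def average_replicates(
    expr: ExpressionMatrix, sample_to_line: dict[str, str] | None = None
) -> pd.DataFrame:
    """Average replicate columns per cell line (genes x lines).

    By default the line is the sample id with a trailing ``_rep<k>``
    stripped; pass an explicit mapping otherwise.
    """
    mapping = {
        s: (sample_to_line[s] if sample_to_line else _default_line_of(s))
        for s in expr.sample_ids
    }
    return expr.values.T.groupby(expr.values.columns.map(mapping)).mean().T


def train_phenotype_model(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    phenotype_name: str,
    genes,
    lambda_grid=None,
    sample_to_line: dict[str, str] | None = None,
) -> RidgeModel:
    """Train one phenotype's ridge model on the cell-line cohort.

    Replicate columns are averaged per line first (so the number of LOOCV
    folds equals the number of lines), genes are standardized on the
    training data, the phenotype is scaled and centered, lambda is chosen by
    LOOCV, and the final model is fit at the optimum. Leave-one-out
    predictions at the chosen lambda are stored for concordance analysis.
    """
    if phenotype_name not in phenotypes.phenotype_names:
        raise ValidationError(f"unknown phenotype {phenotype_name!r}")
    genes = list(genes)
    averaged = average_replicates(expr, sample_to_line).loc[genes]
    lines = list(averaged.columns)
    pheno = phenotypes.values[phenotype_name]
    missing = [ln for ln in lines if ln not in pheno.index or pd.isna(pheno.get(ln))]
    if missing:
        raise ValidationError(
            f"phenotype {phenotype_name!r} missing for cell lines: {missing}"
        )
    y_raw = pheno.loc[lines].to_numpy(dtype=float)
    X_raw = averaged.T.to_numpy(dtype=float)  # lines x genes
    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [genes[i] for i in np.nonzero(sds == 0)[0][:5]]
        raise ValidationError(f"constant genes across training lines: {bad}")
    Xz = (X_raw - means) / sds
    y, y_scale = scale_center(y_raw)
    lam, curve = loocv_select_lambda(Xz, y, lambda_grid)
    fit = fit_ridge(Xz, y, lam)
    cv_pred = loocv_predictions(Xz, y, lam)
    logger.info(
        "trained %s: n=%d lines, p=%d genes, lambda=%.4g",
        phenotype_name, len(lines), len(genes), lam,
    )
    return RidgeModel(
        phenotype_name=phenotype_name,
        gene_ids=genes,
        coefficients=fit.coefficients,
        intercept=fit.intercept,
        lam=lam,
        train_gene_means=means,
        train_gene_sds=sds,
        cv_error_curve=curve,
        n_folds=len(lines),
        cv_predictions={ln: float(v) for ln, v in zip(lines, cv_pred)},
        y_scale=y_scale,
    )


def predict_scores(
    model: RidgeModel,
    expr: ExpressionMatrix,
    standardization: str = "target",
) -> PlasticityScores:
    """Project a trained model onto a (typically tumor) expression matrix.

    ``standardization="target"`` (default) re-standardizes each model gene
    within the target cohort, which is how cell-line-scale coefficients are
    made commensurate with biopsy-scale data; ``"training"`` applies the
    stored training means/sds instead. Model genes absent from the target
    (or constant under target standardization) contribute 0 — i.e. mean
    imputation under standardization. Fails if under half the model genes
    are present.
    """
    if standardization not in ("target", "training"):
        raise ValidationError(f"unknown standardization {standardization!r}")
    present = [g for g in model.gene_ids if g in expr.values.index]
    frac = len(present) / len(model.gene_ids)
    if frac < 0.5:
        raise CoverageError(
            f"only {frac:.1%} of model genes present in target (need >= 50%)"
        )
    if frac < 1.0:
        logger.warning(
            "predict %s: %d/%d model genes present",
            model.phenotype_name, len(present), len(model.gene_ids),
        )
    sub = expr.values.loc[present]  # genes x samples
    X = sub.to_numpy(dtype=float).T  # samples x genes
    idx = [model.gene_ids.index(g) for g in present]
    beta = model.coefficients[idx]
    if standardization == "target":
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        safe = sds > 0
        Z = np.zeros_like(X)
        Z[:, safe] = (X[:, safe] - means[safe]) / sds[safe]
    else:
        means = model.train_gene_means[idx]
        sds = model.train_gene_sds[idx]
        Z = (X - means) / sds
    scores = Z @ beta + model.intercept
    return PlasticityScores(
        sample_ids=expr.sample_ids, scores=scores, model_name=model.phenotype_name
    )


def top_coefficient_genes(model: RidgeModel, k: int = 25) -> tuple[list[str], list[str]]:
    """Top-k positive and top-k negative coefficient genes.

    Positive list sorted by descending coefficient, negative by ascending;
    ties break by gene id. If a sign has fewer than k genes, all available
    are returned with a warning.
    """
    if k < 0:
        raise ValidationError("k must be nonnegative")
    coef = dict(zip(model.gene_ids, model.coefficients))
    pos = sorted((g for g in model.gene_ids if coef[g] > 0),
                 key=lambda g: (-coef[g], g))
    neg = sorted((g for g in model.gene_ids if coef[g] < 0),
                 key=lambda g: (coef[g], g))
    for name, lst in (("positive", pos), ("negative", neg)):
        if len(lst) < k:
            logger.warning(
                "%s: only %d %s-coefficient genes available (k=%d)",
                model.phenotype_name, len(lst), name, k,
            )
    return pos[:k], neg[:k]
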