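"""Model-vs-phenotype concordance and selection of the consolidated models.

Each trained model's leave-one-out predicted training scores are correlated
(Spearman) against every measured phenotype and against every other model's
predictions. Correlations are mapped to z-scores by the Fisher transform
``z = atanh(r) * sqrt(n - 3)`` with a two-sided normal p. Models are then
selected when they both track their own phenotype and agree with the other
selected candidates, by iterative pruning of the least-concordant candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PhenotypeTable
from .exceptions import ValidationError
from .plasticity_ridge import RidgeModel

logger = logging.getLogger(__name__)

_R_CAP = 1.0 - 1e-12


@dataclass
class ConcordanceMatrix:
    correlations: pd.DataFrame  # rows: models, cols: phenotypes + model predictions
    z_scores: pd.DataFrame
    p_values: pd.DataFrame
    n: int
    capped: list[tuple[str, str]] = field(default_factory=list)

    def self_correlation(self, model_name: str) -> float:
        return float(self.correlations.loc[model_name, model_name])

    def mutual_block(self, names: list[str]) -> pd.DataFrame:
        cols = [f"pred:{n}" for n in names]
        return self.correlations.loc[names, cols]

    def write_tsv(self, path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(p, sep="\t", float_format="%.6g")
        return p


def _spearman_r(x, y) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def concordance_matrix(
    models: list[RidgeModel], phenotypes: PhenotypeTable
) -> ConcordanceMatrix:
    """Spearman correlations of LOOCV model predictions against measured
    phenotypes and against other models' predictions.

    Rows are models; columns are the measured phenotypes followed by
    ``pred:<model>`` columns for the prediction-vs-prediction block.
    Correlations with |r| at the +-1 boundary have their Fisher z capped and
    are recorded in ``capped``.
    """
    if not models:
        raise ValidationError("no models supplied")
    lines = sorted(models[0].cv_predictions)
    n = len(lines)
    if n < 4:
        raise ValidationError(f"need >= 4 training lines for Fisher z, got {n}")
    for m in models:
        if sorted(m.cv_predictions) != lines:
            raise ValidationError("models trained on different cell-line sets")
    preds = {
        m.phenotype_name: np.array([m.cv_predictions[ln] for ln in lines])
        for m in models
    }
    pheno_cols = list(phenotypes.phenotype_names)
    cols = pheno_cols + [f"pred:{m.phenotype_name}" for m in models]
    rows = [m.phenotype_name for m in models]
    r = pd.DataFrame(index=rows, columns=cols, dtype=float)
    capped: list[tuple[str, str]] = []
    for m in models:
        for ph in pheno_cols:
            y = phenotypes.values[ph].loc[lines].to_numpy(dtype=float)
            r.loc[m.phenotype_name, ph] = _spearman_r(preds[m.phenotype_name], y)
        for other in models:
            r.loc[m.phenotype_name, f"pred:{other.phenotype_name}"] = _spearman_r(
                preds[m.phenotype_name], preds[other.phenotype_name]
            )
    rv = r.to_numpy(dtype=float)
    at_cap = np.abs(rv) >= _R_CAP
    for i, j in zip(*np.nonzero(at_cap)):
        capped.append((rows[i], cols[j]))
        # |r| = 1 happens routinely for rank correlations at n = 8
        logger.info("correlation at boundary capped: %s vs %s", rows[i], cols[j])
    clipped = np.clip(rv, -_R_CAP, _R_CAP)
    z = np.arctanh(clipped) * np.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ConcordanceMatrix(
        correlations=r,
        z_scores=pd.DataFrame(z, index=rows, columns=cols),
        p_values=pd.DataFrame(p, index=rows, columns=cols),
        n=n,
        capped=capped,
    )


def select_models(
    matrix: ConcordanceMatrix,
    min_self_corr: float = 0.5,
    min_mutual_corr: float = 0.5,
) -> list[str]:
    """Select the mutually-concordant, self-predictive models.

    A model is a candidate when Spearman(LOOCV prediction, own phenotype)
    >= ``min_self_corr``. Candidates are then pruned iteratively: while any
    candidate's median correlation with the other candidates' predictions
    falls below ``min_mutual_corr``, the candidate with the lowest median is
    removed (ties by name). A single surviving candidate passes the mutual
    condition vacuously. Empty selection is returned with a warning.
    """
    for name, v in (("min_self_corr", min_self_corr), ("min_mutual_corr", min_mutual_corr)):
        if not (0 < v < 1):
            raise ValidationError(f"{name} must be in (0, 1), got {v}")
    names = sorted(matrix.correlations.index)
    candidates = [m for m in names if matrix.self_correlation(m) >= min_self_corr]
    while len(candidates) > 1:
        block = matrix.mutual_block(candidates)
        medians = {}
        for m in candidates:
            others = [f"pred:{o}" for o in candidates if o != m]
            medians[m] = float(block.loc[m, others].median())
        worst = min(medians, key=lambda m: (medians[m], m))
        if medians[worst] >= min_mutual_corr:
            break
        candidates.remove(worst)
    if not candidates:
        logger.warning("no model passed the concordance thresholds")
    return candidates
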