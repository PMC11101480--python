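"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a small panel of
training cell lines sequenced in replicate, a latent per-sample
"mesenchymal plasticity" factor s ~ N(0, 1) that drives a block of
informative genes (half with positive, half with negative loadings), six
in-vitro phenotypes of which three (morphology, CDH2, ZEB1) track the
latent factor and three (CD24, CXCR4, VIM) are pure noise, a patient cohort
whose expression carries the same factor, a transcription-factor regulon
embedded among the informative genes alongside decoy sets, and clinical
outcomes (Mandard regression grade, recurrence, overall survival) coupled
to the factor.

Expression is on a log2-like scale: gene g in sample j is
``b_g + w_g * s_j + eps`` with a gene baseline b_g, loading w_g (zero for
noise genes, magnitude ~ ``effect_size`` for informative genes) and i.i.d.
Gaussian noise. Informative genes get higher baselines so they survive a
mean-expression filter in both cohorts, as EMT program genes are robustly
expressed in this tissue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetLibrary,
    PhenotypeTable,
)
from . import data_io
from .exceptions import ConfigError

# fixed generator constants (documented in docs/methods.md)
BASELINE_MEAN = 8.0  # log2-scale baseline expression of a typical gene
BASELINE_SD = 2.0
INFORMATIVE_BASELINE_MEAN = 10.0  # program genes sit in the expressed tail
INFORMATIVE_BASELINE_SD = 1.0
LOADING_LOG_SIGMA = 0.8  # log-sd of informative-gene loading magnitudes
PHENOTYPE_NOISE_SD = 0.3  # measurement noise of concordant phenotypes
PHENOTYPE_SLOPE = 1.0
MANDARD_JITTER_SD = 0.5  # noise between latent plasticity and regression grade
BASE_HAZARD = 1.0 / 40.0  # per month; median OS ~ 28 months at s = 0
LOG_HAZARD_SLOPE = 1.0  # log-hazard increase per unit latent score
N_DECOY_SETS = 25


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 20000
    n_informative: int = 2000
    n_celllines: int = 8
    n_replicates: int = 2
    n_patients: int = 100
    effect_size: float = 1.0
    noise_sd: float = 1.0
    concordant_phenotypes: tuple[str, ...] = ("morphology", "CDH2", "ZEB1")
    discordant_phenotypes: tuple[str, ...] = ("CD24", "CXCR4", "VIM")
    tf_regulon_size: int = 200
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_informative": self.n_informative,
            "n_celllines": self.n_celllines,
            "n_replicates": self.n_replicates,
            "n_patients": self.n_patients,
            "tf_regulon_size": self.tf_regulon_size,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_informative > self.n_genes:
            raise ConfigError("n_informative exceeds n_genes")
        if self.tf_regulon_size > self.n_informative:
            raise ConfigError("tf_regulon_size exceeds n_informative")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if not (0 <= self.censor_rate <= 1):
            raise ConfigError(f"censor_rate must be in [0,1], got {self.censor_rate}")
        if not self.concordant_phenotypes or not self.discordant_phenotypes:
            raise ConfigError("phenotype name lists must be non-empty")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticBundle:
    cellline_expression: ExpressionMatrix
    patient_expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    clinical: ClinicalTable
    latent_scores: pd.Series  # ground truth s, one entry per line and patient
    tf_library: GeneSetLibrary
    causal_tf_name: str
    informative_genes: list[str] = field(default_factory=list)
    loadings: pd.Series | None = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_bundle(config: GeneratorConfig) -> SyntheticBundle:
    """Generate one fully seeded cohort (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    width = max(5, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    lines = [f"CL{i}" for i in range(1, config.n_celllines + 1)]
    patients = [f"PT{i:03d}" for i in range(1, config.n_patients + 1)]

    informative_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_informative, replace=False)
    )
    informative = [genes[i] for i in informative_idx]

    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    baselines[informative_idx] = rng.normal(
        INFORMATIVE_BASELINE_MEAN, INFORMATIVE_BASELINE_SD, size=config.n_informative
    )

    # loadings: half positive, half negative; magnitudes are heavy-tailed
    # around effect_size (log-normal, median = effect_size), so a program
    # has a core of strongly driven genes and a long tail of weak ones
    w = np.zeros(config.n_genes)
    signs = np.ones(config.n_informative)
    signs[config.n_informative // 2 :] = -1.0
    rng.shuffle(signs)
    magnitudes = config.effect_size * rng.lognormal(
        mean=0.0, sigma=LOADING_LOG_SIGMA, size=config.n_informative
    )
    w[informative_idx] = signs * magnitudes

    s_lines = rng.normal(size=config.n_celllines)
    s_patients = rng.normal(size=config.n_patients)

    # cell-line expression: replicate columns per line
    cl_cols, cl_ids = [], []
    for li, line in enumerate(lines):
        for r in range(1, config.n_replicates + 1):
            eps = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            cl_cols.append(baselines + w * s_lines[li] + eps)
            cl_ids.append(f"{line}_rep{r}")
    cellline_expr = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cl_cols), index=genes, columns=cl_ids),
        cohort="cell_line",
    )

    pt_eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_patients))
    patient_expr = ExpressionMatrix(
        pd.DataFrame(
            baselines[:, None] + np.outer(w, s_patients) + pt_eps,
            index=genes,
            columns=patients,
        ),
        cohort="tumor",
    )

    # phenotypes: concordant track s with small noise, discordant pure noise
    pheno = {}
    for name in config.concordant_phenotypes:
        pheno[name] = PHENOTYPE_SLOPE * s_lines + rng.normal(
            0.0, PHENOTYPE_NOISE_SD, size=config.n_celllines
        )
    for name in config.discordant_phenotypes:
        pheno[name] = rng.normal(size=config.n_celllines)
    phenotypes = PhenotypeTable(pd.DataFrame(pheno, index=lines))

    # TF library: the causal regulon is a broad subset of the positively
    # loaded program genes (a TF's consensus target set covers much of the
    # program it drives); decoys are random gene sets from the whole universe
    causal_name = "TF_CAUSAL"
    w_of = dict(zip(informative, w[informative_idx]))
    pool = sorted(g for g in informative if w_of[g] > 0)
    if len(pool) < config.tf_regulon_size:
        pool = sorted(informative)
    regulon = sorted(
        rng.choice(pool, size=config.tf_regulon_size, replace=False).tolist()
    )
    sets: dict[str, tuple[str, ...]] = {causal_name: tuple(regulon)}
    for d in range(1, N_DECOY_SETS + 1):
        members = sorted(
            rng.choice(genes, size=config.tf_regulon_size, replace=False).tolist()
        )
        sets[f"TF_DECOY{d:02d}"] = tuple(members)
    tf_library = GeneSetLibrary(sets)

    # clinical outcomes coupled to the latent factor
    grade_latent = s_patients + rng.normal(0.0, MANDARD_JITTER_SD, config.n_patients)
    q25, q50, q75 = np.quantile(grade_latent, [0.25, 0.5, 0.75])
    mandard = (
        1
        + (grade_latent > q25).astype(int)
        + (grade_latent > q50).astype(int)
        + (grade_latent > q75).astype(int)
    )
    recurrence = rng.uniform(size=config.n_patients) < _sigmoid(s_patients)
    hazard = BASE_HAZARD * np.exp(LOG_HAZARD_SLOPE * s_patients)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=config.n_patients) < config.censor_rate
    os_time = np.where(
        censored, rng.uniform(0.0, 1.0, config.n_patients) * event_time, event_time
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "mandard": pd.array(mandard, dtype="Int64"),
                "recurrence": pd.array(recurrence, dtype="boolean"),
                "os_time": os_time,
                "os_event": pd.array(~censored, dtype="boolean"),
            },
            index=patients,
        )
    )

    latent = pd.Series(
        np.concatenate([s_lines, s_patients]), index=lines + patients, name="latent_s"
    )
    return SyntheticBundle(
        cellline_expression=cellline_expr,
        patient_expression=patient_expr,
        phenotypes=phenotypes,
        clinical=clinical,
        latent_scores=latent,
        tf_library=tf_library,
        causal_tf_name=causal_name,
        informative_genes=informative,
        loadings=pd.Series(w, index=genes, name="loading"),
    )


def write_bundle(bundle: SyntheticBundle, directory) -> dict[str, Path]:
    """Write a bundle to ``directory`` and return a manifest of paths.

    Ground-truth files (latent scores, causal TF name, loadings) go to a
    ``ground_truth/`` subdirectory that the pipeline never reads; leakage is
    detectable by path convention.
    """
    d = data_io.ensure_writable_dir(directory)
    gt = data_io.ensure_writable_dir(d / "ground_truth")
    manifest = {
        "cellline_expression": data_io.write_expression(
            bundle.cellline_expression, d / "celllines.tsv"
        ),
        "patient_expression": data_io.write_expression(
            bundle.patient_expression, d / "patients.tsv"
        ),
        "phenotypes": data_io.write_phenotypes(bundle.phenotypes, d / "phenotypes.csv"),
        "clinical": data_io.write_clinical(bundle.clinical, d / "clinical.csv"),
        "tf_library": data_io.write_gmt(bundle.tf_library, d / "tf_library.gmt"),
        "latent_scores": data_io.write_series_csv(
            bundle.latent_scores, gt / "latent_scores.csv", "sample_id", "latent_s"
        ),
    }
    (gt / "causal_tf.txt").write_text(bundle.causal_tf_name + "\n")
    manifest["causal_tf"] = gt / "causal_tf.txt"
    if bundle.loadings is not None:
        manifest["loadings"] = data_io.write_series_csv(
            bundle.loadings, gt / "loadings.csv", "gene_id", "loading"
        )
    return manifest
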