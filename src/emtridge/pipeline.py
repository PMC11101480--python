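"""End-to-end orchestration: simulate -> filter -> train -> select ->
project -> enrich -> associate, with a reproducible on-disk layout.

Every stage reads its inputs from files (either the configured input paths
or the outputs of earlier stages under the run directory) and writes plain
text outputs, so identical config + inputs give byte-identical outputs and
manifest hashes. Ground-truth files written by the simulator live under
``data/ground_truth/`` and are never read by any stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as _field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .clinical_assoc import (
    dichotomize_median,
    km_estimate,
    logrank_test,
    mandard_association,
    welch_t,
)
from .containers import ExpressionMatrix
from .exceptions import ValidationError
from .model_concordance import concordance_matrix, select_models
from .plasticity_ridge import (
    RidgeModel,
    predict_scores,
    train_phenotype_model,
)
from .preprocess import FilterParams, expression_filter, normalize_log2, variance_filter
from .synthetic_data import GeneratorConfig, generate_bundle, write_bundle
from .tf_enrichment import fisher_enrichment, pool_top_genes, write_results

logger = logging.getLogger(__name__)

INPUT_KEYS = ("celllines", "patients", "phenotypes", "clinical", "tf_library")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    inputs: dict[str, Path] = _field(default_factory=dict)
    generator: dict = _field(default_factory=dict)
    normalize: bool = False
    filter_params: FilterParams = _field(default_factory=FilterParams)
    lambda_grid: np.ndarray | None = None
    top_k: int = 25
    min_self_corr: float = 0.5
    min_mutual_corr: float = 0.5
    standardization: str = "target"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path.cwd()
        if "outdir" not in raw:
            raise ValidationError("config must set 'outdir'")
        inputs = {
            k: (base / v if not Path(v).is_absolute() else Path(v))
            for k, v in (raw.get("inputs") or {}).items()
        }
        unknown = set(inputs) - set(INPUT_KEYS)
        if unknown:
            raise ValidationError(f"unknown input keys: {sorted(unknown)}")
        fp = raw.get("filter") or {}
        grid_spec = raw.get("lambda_grid")
        grid = None
        if grid_spec:
            grid = np.logspace(
                np.log10(float(grid_spec["min"])),
                np.log10(float(grid_spec["max"])),
                int(grid_spec["num"]),
            )
        return cls(
            outdir=base / raw["outdir"],
            seed=int(raw.get("seed", 0)),
            inputs=inputs,
            generator=dict(raw.get("generator") or {}),
            normalize=bool(raw.get("normalize", False)),
            filter_params=FilterParams(
                expressed_fraction=float(fp.get("expressed_fraction", 0.33)),
                n_variable=int(fp.get("n_variable", 5000)),
            ),
            lambda_grid=grid,
            top_k=int(raw.get("top_k", 25)),
            min_self_corr=float(
                (raw.get("concordance") or {}).get("min_self_corr", 0.5)
            ),
            min_mutual_corr=float(
                (raw.get("concordance") or {}).get("min_mutual_corr", 0.5)
            ),
            standardization=str(raw.get("standardization", "target")),
        )

    def validate_inputs(self, require: bool) -> None:
        """Check that every referenced input exists (before any stage runs)."""
        for key, p in self.inputs.items():
            if not Path(p).is_file():
                raise ValidationError(f"configured input {key!r} not found: {p}")
        if require:
            for key in INPUT_KEYS:
                if key not in self.resolved_inputs():
                    raise ValidationError(
                        f"input {key!r} neither configured nor simulated yet"
                    )

    def resolved_inputs(self) -> dict[str, Path]:
        """Configured paths, falling back to the simulate stage's outputs."""
        data = Path(self.outdir) / "data"
        defaults = {
            "celllines": data / "celllines.tsv",
            "patients": data / "patients.tsv",
            "phenotypes": data / "phenotypes.csv",
            "clinical": data / "clinical.csv",
            "tf_library": data / "tf_library.gmt",
        }
        out = {}
        for key in INPUT_KEYS:
            p = self.inputs.get(key, defaults[key])
            if Path(p).is_file():
                out[key] = Path(p)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _log_stage(name: str, t0: float, **shapes) -> dict:
    info = {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **shapes}
    logger.info("stage %s done: %s", name, shapes)
    return info


def stage_simulate(config: RunConfig) -> dict:
    t0 = time.perf_counter()
    gen = GeneratorConfig(**{"seed": config.seed, **config.generator})
    bundle = generate_bundle(gen)
    write_bundle(bundle, Path(config.outdir) / "data")
    return _log_stage(
        "simulate",
        t0,
        n_genes=gen.n_genes,
        n_celllines=gen.n_celllines,
        n_patients=gen.n_patients,
    )


def _load_expression(config: RunConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    inputs = config.resolved_inputs()
    cl = data_io.read_expression(inputs["celllines"], cohort="cell_line")
    pt = data_io.read_expression(inputs["patients"], cohort="tumor")
    if config.normalize:
        cl = normalize_log2(cl)
        pt = normalize_log2(pt)
    return cl, pt


def stage_preprocess(config: RunConfig) -> dict:
    t0 = time.perf_counter()
    config.validate_inputs(require=True)
    cl, pt = _load_expression(config)
    expressed = expression_filter(cl, pt, config.filter_params)
    selected = variance_filter(cl, expressed, config.filter_params)
    out = Path(config.outdir) / "preprocess" / "selected_genes.txt"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("\n".join(selected) + "\n")
    return _log_stage(
        "preprocess", t0, n_expressed=len(expressed), n_selected=len(selected)
    )


def _selected_genes(config: RunConfig) -> list[str]:
    p = Path(config.outdir) / "preprocess" / "selected_genes.txt"
    if not p.is_file():
        raise ValidationError("preprocess stage has not run (selected_genes.txt missing)")
    return p.read_text().split()


def stage_train(config: RunConfig) -> dict:
    """Train one ridge model per phenotype, then compute the concordance
    matrix and the model selection."""
    t0 = time.perf_counter()
    config.validate_inputs(require=True)
    inputs = config.resolved_inputs()
    cl, _ = _load_expression(config)
    phenotypes = data_io.read_phenotypes(inputs["phenotypes"])
    genes = _selected_genes(config)
    model_dir = Path(config.outdir) / "models"
    models = []
    for name in phenotypes.phenotype_names:
        model = train_phenotype_model(
            cl, phenotypes, name, genes, lambda_grid=config.lambda_grid
        )
        model.to_json(model_dir / f"model_{name}.json")
        models.append(model)
    matrix = concordance_matrix(models, phenotypes)
    conc_dir = Path(config.outdir) / "concordance"
    matrix.write_tsv(conc_dir / "matrix.tsv")
    selected = select_models(matrix, config.min_self_corr, config.min_mutual_corr)
    (conc_dir / "selection.json").parent.mkdir(parents=True, exist_ok=True)
    (conc_dir / "selection.json").write_text(
        json.dumps(
            {
                "selected": selected,
                "min_self_corr": config.min_self_corr,
                "min_mutual_corr": config.min_mutual_corr,
            },
            indent=1,
        )
    )
    return _log_stage(
        "train",
        t0,
        n_models=len(models),
        n_folds=models[0].n_folds,
        n_selected=len(selected),
    )


def _load_models(config: RunConfig, names=None) -> list[RidgeModel]:
    model_dir = Path(config.outdir) / "models"
    paths = sorted(model_dir.glob("model_*.json"))
    if not paths:
        raise ValidationError("train stage has not run (no model files)")
    models = [RidgeModel.from_json(p) for p in paths]
    if names is not None:
        by_name = {m.phenotype_name: m for m in models}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise ValidationError(f"missing trained models: {missing}")
        models = [by_name[n] for n in names]
    return models


def _load_selection(config: RunConfig) -> list[str]:
    p = Path(config.outdir) / "concordance" / "selection.json"
    if not p.is_file():
        raise ValidationError("selection missing; run the train stage first")
    return json.loads(p.read_text())["selected"]


def stage_predict(config: RunConfig) -> dict:
    t0 = time.perf_counter()
    selected = _load_selection(config)
    if not selected:
        raise ValidationError("no models selected; pipeline halts before prediction")
    models = _load_models(config, selected)
    _, pt = _load_expression(config)
    rows = []
    for model in models:
        sc = predict_scores(model, pt, standardization=config.standardization)
        rows.append(sc.as_series())
    scores = pd.concat(rows, axis=1)
    out = Path(config.outdir) / "scores" / "scores.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out, float_format="%.17g", index_label="sample_id")
    return _log_stage(
        "predict", t0, n_models=len(models), n_samples=scores.shape[0]
    )


def stage_enrich(config: RunConfig) -> dict:
    t0 = time.perf_counter()
    selected = _load_selection(config)
    if not selected:
        raise ValidationError("no models selected; nothing to enrich")
    models = _load_models(config, selected)
    inputs = config.resolved_inputs()
    library = data_io.read_gmt(inputs["tf_library"])
    background = _selected_genes(config)
    pooled = pool_top_genes(models, config.top_k)
    pooled_in_bg = [g for g in pooled if g in set(background)]
    results = fisher_enrichment(pooled_in_bg, library, background)
    enr_dir = Path(config.outdir) / "enrichment"
    enr_dir.mkdir(parents=True, exist_ok=True)
    (enr_dir / "pooled_genes.txt").write_text("\n".join(pooled) + "\n")
    write_results(results, enr_dir / "results.tsv")
    return _log_stage(
        "enrich", t0, n_pooled=len(pooled), n_sets_tested=len(results)
    )


def stage_associate(config: RunConfig) -> dict:
    """Relate each selected model's patient scores to clinical outcome:
    recurrence (one-sided Welch t, higher score in recurrent patients),
    Mandard grade (pairwise Mann-Whitney), and overall survival (median
    dichotomization + Kaplan-Meier / log-rank)."""
    t0 = time.perf_counter()
    inputs = config.resolved_inputs()
    clinical = data_io.read_clinical(inputs["clinical"])
    score_path = Path(config.outdir) / "scores" / "scores.csv"
    if not score_path.is_file():
        raise ValidationError("scores missing; run the predict stage first")
    scores = pd.read_csv(score_path, index_col=0)
    cdf = clinical.values.reindex(scores.index)
    rows = []
    clin_dir = Path(config.outdir) / "clinical"
    clin_dir.mkdir(parents=True, exist_ok=True)
    for model_name in scores.columns:
        s = scores[model_name]
        rec = cdf["recurrence"]
        keep = rec.notna()
        rec_bool = rec.fillna(False).astype(bool)
        res = welch_t(
            s[keep & rec_bool], s[keep & ~rec_bool], alternative="greater"
        )
        rows.append((model_name, "recurrence_welch_one_sided", res))
        for r in mandard_association(
            s.to_numpy(), cdf["mandard"].to_numpy(dtype=float, na_value=np.nan)
        ):
            rows.append((model_name, r.label.replace(" ", "_"), r))
        surv = cdf[cdf["os_event"].notna() & cdf["os_time"].notna()]
        labels = dichotomize_median(s.loc[surv.index])
        times = surv["os_time"].to_numpy(dtype=float)
        events = surv["os_event"].to_numpy(dtype=bool)
        lr = logrank_test(times, events, labels)
        rows.append((model_name, "os_logrank_median_split", lr))
        for grp in ("high", "low"):
            mask = labels == grp
            if mask.sum() == 0:
                continue
            curve = km_estimate(times[mask], events[mask])
            pd.DataFrame(
                {
                    "time": curve.event_times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                    "events": curve.events,
                }
            ).to_csv(
                clin_dir / f"km_{model_name}_{grp}.csv",
                index=False,
                float_format="%.6g",
            )
    report = pd.DataFrame(
        [
            {
                "model": m,
                "comparison": label,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
                "n": "/".join(str(x) for x in r.n_per_group),
            }
            for m, label, r in rows
        ]
    )
    report.to_csv(
        clin_dir / "associations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return _log_stage("associate", t0, n_tests=len(report))


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "predict": stage_predict,
    "enrich": stage_enrich,
    "associate": stage_associate,
}


def run_all(config: RunConfig, simulate: bool | None = None) -> dict:
    """Run the full chain and write a manifest of hashes and stage logs.

    ``simulate=None`` auto-detects: the simulate stage runs only when no
    input files are configured. Any stage failure aborts with the stage
    name; partial outputs are retained.
    """
    config.validate_inputs(require=False)
    do_sim = simulate if simulate is not None else not config.inputs
    order = (["simulate"] if do_sim else []) + [
        "preprocess", "train", "predict", "enrich", "associate",
    ]
    stage_logs = []
    for name in order:
        try:
            stage_logs.append(STAGES[name](config))
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    inputs = config.resolved_inputs()
    outdir = Path(config.outdir)
    output_files = sorted(
        p
        for p in outdir.rglob("*")
        if p.is_file() and "ground_truth" not in p.parts and p.name != "manifest.json"
    )
    manifest = {
        "package": "emtridge",
        "version": _pkg_version("emtridge"),
        "seed": config.seed,
        "config": {
            "normalize": config.normalize,
            "expressed_fraction": config.filter_params.expressed_fraction,
            "n_variable": config.filter_params.n_variable,
            "top_k": config.top_k,
            "min_self_corr": config.min_self_corr,
            "min_mutual_corr": config.min_mutual_corr,
            "standardization": config.standardization,
        },
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
        "output_hashes": {
            str(p.relative_to(outdir)): _sha256(p) for p in output_files
        },
        "stages": stage_logs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
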