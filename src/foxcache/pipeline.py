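"""End-to-end driver: raw files in, analysis artifacts out.

Stages run in workflow order — read inputs, prepare the training set
from annotations, extract features, cross-validate the algorithm
roster, select and refit the best model, annotate every burst, compute
activity budgets, fuse with GPS, apply the exclusion cascade, and fit
the caching model. Every stage logs input/output/exclusion counts; a
failure halts with the stage name attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, glmm, io as fio, spatiotemporal, training
from .config import PipelineConfig
from .features import FEATURE_NAMES, compute_feature_matrix

log = logging.getLogger("foxcache")

INPUT_FILES = {
    "accelerometry": "accelerometry.csv",
    "gps": "gps.csv",
    "annotations": "annotations.csv",
    "raster": "goose_density.asc",
    "dens": "dens.csv",
    "metadata": "metadata.csv",
    "season": "season.csv",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    training_manifest: pd.DataFrame
    feature_table: pd.DataFrame
    cv_results: dict
    selected: str
    window_labels: pd.DataFrame
    budget: pd.Series
    filter_report: spatiotemporal.FilterReport
    analysis_table: pd.DataFrame
    fit: glmm.GlmmFit | None
    outputs: dict[str, Path]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with stage context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    cfg.validate()
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d input=%s", cfg.seed, input_dir)

    @_stage("read-inputs")
    def read_inputs():
        missing = [f for f in INPUT_FILES.values() if not (input_dir / f).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files in {input_dir}: {missing}")
        bursts, signals = fio.read_accelerometry(input_dir / INPUT_FILES["accelerometry"])
        return {
            "bursts": bursts,
            "signals": signals,
            "gps": fio.read_gps(input_dir / INPUT_FILES["gps"]),
            "annotations": fio.read_annotations(input_dir / INPUT_FILES["annotations"]),
            "raster": fio.read_raster(input_dir / INPUT_FILES["raster"]),
            "dens": fio.read_dens(input_dir / INPUT_FILES["dens"]),
            "metadata": fio.read_metadata(input_dir / INPUT_FILES["metadata"]),
            "season": fio.read_season(input_dir / INPUT_FILES["season"]),
        }

    data = read_inputs()
    n_bursts = len(data["bursts"])
    rate = 50.0
    log.info("loaded %d bursts, %d fixes", n_bursts, len(data["gps"]))

    @_stage("training-prep")
    def prepare_training():
        events = training.synchronize_annotations(
            data["annotations"], cfg.annotation_clock_offset_s
        )
        seqs = training.extract_training_sequences(
            data["bursts"], data["signals"], events, window_s=cfg.window_s, rate=rate
        )
        return training.sequences_to_arrays(seqs)

    train_signals, train_labels, manifest = prepare_training()
    log.info("training sequences: %d", len(train_labels))

    @_stage("features")
    def features():
        feats = compute_feature_matrix(train_signals)
        table = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
        table.insert(0, "sequence_id", manifest["sequence_id"].to_numpy())
        table["label"] = train_labels
        return feats, table

    feats, feature_table = features()

    @_stage("cross-validation")
    def crossval():
        counts = pd.Series(train_labels).value_counts()
        stratified = bool((counts >= cfg.n_folds).all())
        if not stratified:
            log.warning("rare class below k: falling back to unstratified folds")
        return classification.crossvalidate(
            feats,
            train_labels,
            algorithms=cfg.algorithms,
            k=cfg.n_folds,
            seed=cfg.seed,
            stratified=stratified,
        )

    cv_results = crossval()

    @_stage("model-selection")
    def select():
        name = classification.select_model(cv_results, cfg.selection_criterion)
        model = classification.fit_final_model(feats, train_labels, name, seed=cfg.seed)
        return name, model

    selected, model = select()
    log.info("selected algorithm: %s", selected)

    @_stage("annotate")
    def annotate():
        return classification.annotate_bursts(
            model,
            data["signals"],
            burst_ids=data["bursts"]["burst_id"].to_numpy(),
        )

    window_labels = annotate()

    @_stage("budget")
    def budget_stage():
        return classification.activity_budget(window_labels["label"])

    budget = budget_stage()

    @_stage("spatial-join")
    def spatial_join():
        matched = spatiotemporal.match_gps(
            data["bursts"], data["gps"], max_gap_s=cfg.max_gps_gap_s
        )
        matched = matched[matched["x_m"].notna()].reset_index(drop=True)
        cov = spatiotemporal.annotate_covariates(
            matched, data["raster"], data["dens"], data["season"], data["metadata"]
        )
        report = spatiotemporal.apply_filters(
            cov,
            fio.capture_times(data["metadata"]),
            den_buffer_m=cfg.den_buffer_m,
            capture_exclusion_h=cfg.capture_exclusion_h,
        )
        table = spatiotemporal.build_analysis_table(window_labels, report.retained)
        return report, table

    filter_report, analysis = spatial_join()

    @_stage("caching-model")
    def fit_model():
        both_periods = analysis["period"].isin(["incubation", "brooding"])
        tab = analysis[both_periods].copy()
        if tab.empty or tab["digging"].nunique() < 2 or tab["fox_id"].nunique() < 2:
            log.warning("analysis table too degenerate for the mixed model; skipping fit")
            return None, tab
        z, center, scale = glmm.standardize(
            tab["density"].to_numpy(), two_sd=cfg.two_sd_standardization
        )
        tab["density_std"] = z
        try:
            fit = glmm.fit_glmm_cloglog(tab, density_center=center, density_scale=scale)
        except ValueError as exc:
            # tiny campaigns can lack a factor level entirely
            log.warning("mixed model not fitted: %s", exc)
            return None, tab
        return fit, tab

    fit, analysis_std = fit_model()

    @_stage("write-outputs")
    def write_outputs():
        out: dict[str, Path] = {}
        feature_table.to_csv(output_dir / "training_features.csv", index=False)
        out["training_features.csv"] = output_dir / "training_features.csv"
        (output_dir / "feature_names.txt").write_text("\n".join(FEATURE_NAMES) + "\n")

        metric_rows = []
        for name, res in cv_results.items():
            m = res.metrics.rounded()
            m.insert(0, "algorithm", name)
            m.insert(1, "category", m.index)
            metric_rows.append(m.reset_index(drop=True))
            cm = res.confusion.to_frame()
            cm.to_csv(output_dir / f"confusion_{name}.csv")
            out[f"confusion_{name}.csv"] = output_dir / f"confusion_{name}.csv"
        pd.concat(metric_rows, ignore_index=True).to_csv(
            output_dir / "cv_metrics.csv", index=False
        )
        out["cv_metrics.csv"] = output_dir / "cv_metrics.csv"
        (output_dir / "selected_model.txt").write_text(selected + "\n")

        window_labels.to_csv(output_dir / "window_labels.csv", index=False)
        out["window_labels.csv"] = output_dir / "window_labels.csv"
        budget.rename_axis("behaviour").to_frame().to_csv(output_dir / "activity_budget.csv")
        out["activity_budget.csv"] = output_dir / "activity_budget.csv"
        filter_report.to_frame().to_csv(output_dir / "exclusions.csv", index=False)
        out["exclusions.csv"] = output_dir / "exclusions.csv"
        analysis_std.to_csv(output_dir / "analysis_table.csv", index=False)
        out["analysis_table.csv"] = output_dir / "analysis_table.csv"

        if fit is not None:
            fit.fixed.rename_axis("term").to_csv(output_dir / "glmm_coefficients.csv")
            out["glmm_coefficients.csv"] = output_dir / "glmm_coefficients.csv"
            pd.DataFrame(
                {
                    "component": ["fox_id", "year"],
                    "variance": [fit.var_fox, fit.var_year],
                    "sd": [fit.sd_fox, fit.sd_year],
                }
            ).to_csv(output_dir / "glmm_variances.csv", index=False)
            out["glmm_variances.csv"] = output_dir / "glmm_variances.csv"
            grid = _prediction_grid(analysis_std)
            preds = glmm.predict_probability(fit, grid, ci=True)
            preds.to_csv(output_dir / "glmm_predictions.csv", index=False)
            out["glmm_predictions.csv"] = output_dir / "glmm_predictions.csv"
        return out

    outputs = write_outputs()
    log.info("pipeline done: %d artifacts in %s", len(outputs), output_dir)
    return PipelineResult(
        training_manifest=manifest,
        feature_table=feature_table,
        cv_results=cv_results,
        selected=selected,
        window_labels=window_labels,
        budget=budget,
        filter_report=filter_report,
        analysis_table=analysis_std,
        fit=fit,
        outputs=outputs,
    )


def _prediction_grid(analysis: pd.DataFrame) -> pd.DataFrame:
    dgrid = np.linspace(
        float(analysis["density"].min()), float(analysis["density"].max()), 25
    )
    frames = []
    for period in sorted(analysis["period"].unique()):
        frames.append(
            pd.DataFrame(
                {
                    "density": dgrid,
                    "period": period,
                    "sex": "M",
                    "status": "reproductive",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_report(output_dir: str | Path) -> str:
    """Markdown summary of a pipeline run (metric, confusion, budget,
    coefficient tables)."""
    output_dir = Path(output_dir)
    parts = ["# Pipeline report\n"]
    selected = (output_dir / "selected_model.txt").read_text().strip()
    parts.append(f"Selected algorithm: **{selected}**\n")
    metrics = pd.read_csv(output_dir / "cv_metrics.csv")
    parts.append("## Cross-validated classification performance\n")
    parts.append(metrics.to_string(index=False))
    cm_path = output_dir / f"confusion_{selected}.csv"
    if cm_path.exists():
        parts.append("\n## Confusion matrix (selected model, pooled out-of-fold)\n")
        parts.append(pd.read_csv(cm_path, index_col=0).to_string())
    parts.append("\n## Activity budget\n")
    parts.append(pd.read_csv(output_dir / "activity_budget.csv").to_string(index=False))
    parts.append("\n## Exclusion cascade\n")
    parts.append(pd.read_csv(output_dir / "exclusions.csv").to_string(index=False))
    coeff = output_dir / "glmm_coefficients.csv"
    if coeff.exists():
        parts.append("\n## Caching model (cloglog GLMM)\n")
        parts.append(pd.read_csv(coeff).round(3).to_string(index=False))
        parts.append("\n")
        parts.append(pd.read_csv(output_dir / "glmm_variances.csv").round(4).to_string(index=False))
    text = "\n".join(parts) + "\n"
    (output_dir / "report.md").write_text(text)
    return text
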