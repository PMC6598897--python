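"""End-to-end two-stage workflow orchestration.

``run_pipeline`` executes: anchor-visit filter -> train/test split (test
baselines kept in training) -> percentile-transform fit -> stage-1 fits
for each requested family -> WAIC/LOOIC comparison -> model-averaging
weights -> trajectory forecasts on test follow-ups -> MissForest
imputation and forest training -> diagnosis forecasts -> per-time-point
metrics.  Every stage writes an artifact under the output directory and a
stage-tagged log line; a manifest records the config hash and seeds so
deterministic stages reproduce bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort
from .data import (
    DX_LABELS,
    LongitudinalDataset,
    build_training_split,
    filter_visits_missing_anchor,
    read_long_table,
)
from .errors import ConfigurationError, ValidationError
from .metrics import (
    balanced_class_accuracy,
    confusion_matrix,
    mean_absolute_error,
    overall_accuracy,
    overall_bca,
    weighted_aggregate_bca,
    weighted_error_score,
)
from .stage1 import (
    MCMCConfig,
    ModelSpec,
    ci_profile,
    compute_looic,
    compute_model_weights,
    compute_waic,
    fit_model,
    model_average,
    predict_trajectories,
)
from .stage2 import (
    MissForestImputer,
    build_feature_table,
    predict_diagnosis,
    train_diagnosis_forest,
)
from .transform import dataset_to_percentiles, fit_transform_from_dataset

log = logging.getLogger("adprogress.pipeline")


@dataclass
class PipelineConfig:
    """One config object governing the whole two-stage run."""

    simulate: CohortConfig | None = None
    observations_csv: str | None = None
    covariates_csv: str | None = None
    diagnoses_csv: str | None = None
    anchor_marker: str = "CDRSB"
    families: tuple[str, ...] = ("IMM", "JMM", "LTJMM")
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    bma_method: str = "pseudo-bma"
    covariates: tuple[str, ...] = ("age_bl", "sex", "apoe4", "dx_bl")
    stage2_include_baseline_dx: bool = True
    stage2_n_trees: int = 100
    test_fraction: float = 0.3
    test_subject_ids: tuple[str, ...] | None = None
    eval_times: tuple[float, ...] | None = None
    out_dir: str = "adprogress_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.families:
            raise ConfigurationError("at least one model family is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        data = raw.get("data", {})
        if "simulate" in data:
            sim = dict(data["simulate"])
            for key in ("markers", "visit_times"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulate"] = CohortConfig(**sim)
        else:
            kwargs["observations_csv"] = data.get("observations")
            kwargs["covariates_csv"] = data.get("covariates")
            kwargs["diagnoses_csv"] = data.get("diagnoses")
        mc = dict(raw.get("mcmc", {}))
        profile = mc.pop("profile", None)
        if profile == "ci":
            kwargs["mcmc"] = ci_profile(mc.get("seed", raw.get("seed", 0)))
        elif mc:
            kwargs["mcmc"] = MCMCConfig(**mc)
        st2 = raw.get("stage2", {})
        if "include_baseline_dx" in st2:
            kwargs["stage2_include_baseline_dx"] = bool(st2["include_baseline_dx"])
        if "n_trees" in st2:
            kwargs["stage2_n_trees"] = int(st2["n_trees"])
        for key in (
            "anchor_marker", "bma_method", "test_fraction", "out_dir", "seed", "eval_times",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "families" in raw:
            kwargs["families"] = tuple(raw["families"])
        if "covariates" in raw:
            kwargs["covariates"] = tuple(raw["covariates"])
        if "test_subject_ids" in raw:
            kwargs["test_subject_ids"] = tuple(raw["test_subject_ids"])
        if kwargs.get("eval_times") is not None:
            kwargs["eval_times"] = tuple(kwargs["eval_times"])
        return cls(**kwargs)

    def fingerprint(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items()}
            return str(o)

        blob = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_dataset(config: PipelineConfig) -> LongitudinalDataset:
    if config.simulate is not None:
        dataset, _ = simulate_cohort(config.simulate)
        return dataset
    if not (config.observations_csv and config.covariates_csv):
        raise ConfigurationError("either a simulation config or CSV paths are required")
    return read_long_table(
        config.observations_csv, config.covariates_csv, config.diagnoses_csv
    )


def metrics_by_time(
    truth_dx: pd.DataFrame, pred_dx: pd.DataFrame, eval_times=None
) -> pd.DataFrame:
    """Per-time-point accuracy and balanced class accuracy.

    Joins on (subject_id, time_years).  Per-class BCA is reported where
    the one-vs-rest reduction is non-degenerate at that time point;
    ``bca_overall`` averages the defined classes.
    """
    merged = truth_dx.merge(pred_dx, on=["subject_id", "time_years"], how="inner")
    if len(merged) == 0:
        raise ValidationError("no overlapping (subject, time) rows between truth and predictions")
    times = sorted(merged["time_years"].unique()) if eval_times is None else list(eval_times)
    rows = []
    for t in times:
        at = merged[merged["time_years"] == t]
        if len(at) == 0:
            continue
        cm = confusion_matrix(at["dx"], at["dx_pred"], DX_LABELS)
        row = {"time_years": t, "n": len(at), "accuracy": overall_accuracy(cm)}
        bcas = {}
        for lab in DX_LABELS:
            try:
                bcas[lab] = balanced_class_accuracy(cm, lab)
            except ValidationError:
                bcas[lab] = np.nan
        defined = [v for v in bcas.values() if np.isfinite(v)]
        row["bca_overall"] = float(np.mean(defined)) if defined else np.nan
        for lab in DX_LABELS:
            row[f"bca_{lab}"] = bcas[lab]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full two-stage workflow; returns the evaluation report."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"config_hash": config.fingerprint(), "seed": config.seed}

    stage = "load"
    try:
        dataset = _load_dataset(config)
        log.info("[load] %d subjects, %d observation rows", len(dataset.subjects), dataset.n_rows())

        stage = "filter"
        dataset = filter_visits_missing_anchor(dataset, config.anchor_marker)
        log.info("[filter] %d rows retain the anchor %s", dataset.n_rows(), config.anchor_marker)

        stage = "split"
        if config.test_subject_ids is not None:
            test_ids = list(config.test_subject_ids)
        else:
            subs = dataset.subjects
            n_test = max(1, int(round(config.test_fraction * len(subs))))
            test_ids = sorted(rng.choice(subs, size=n_test, replace=False).tolist())
        train, test_followup = build_training_split(dataset, test_ids)
        log.info("[split] train rows %d / test follow-up rows %d", train.n_rows(), test_followup.n_rows())

        stage = "transform"
        transform = fit_transform_from_dataset(train, weight_by="visit")
        transform.to_json(out / "transform.json")
        train_pct = dataset_to_percentiles(train, transform)

        stage = "stage1-fit"
        fits, comparison, elpds = {}, [], {}
        for fam in config.families:
            covs = tuple(c for c in config.covariates if not (fam == "LTJMM" and c == "dx_bl"))
            spec = ModelSpec(fam, tuple(train.marker_panel), covariates=covs)
            draws = fit_model(spec, train_pct, config.mcmc)
            draws.save(out / f"fit_{fam}")
            looic, elpd_i, _ = compute_looic(draws, return_pointwise=True)
            waic = compute_waic(draws)
            fits[fam] = draws
            elpds[fam] = elpd_i
            comparison.append({"model": fam, "WAIC": waic, "LOOIC": looic})
            log.info("[stage1-fit] %s: WAIC %.1f LOOIC %.1f", fam, waic, looic)
        comparison = pd.DataFrame(comparison).sort_values("LOOIC").reset_index(drop=True)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        report["model_comparison"] = comparison.to_dict(orient="records")

        stage = "bma-weights"
        if len(fits) >= 2:
            weights = compute_model_weights(fits, method=config.bma_method, elpd_pointwise=elpds)
            report["model_weights"] = weights.as_dict()
            log.info("[bma-weights] %s", weights.as_dict())
        else:
            weights = None

        stage = "stage1-predict"
        followup_times = {
            sid: sorted(grp["time_years"].unique())
            for sid, grp in test_followup.observations.groupby("subject_id")
        }
        pred_subjects = sorted(followup_times)
        predictions = {}
        for fam, draws in fits.items():
            ps = predict_trajectories(draws, transform, pred_subjects, followup_times)
            ps.to_csv(out / f"predictions_{fam}.csv")
            predictions[fam] = ps
        if weights is not None:
            bma = model_average([predictions[f] for f in fits], weights)
            bma.to_csv(out / "predictions_BMA.csv")
            predictions["BMA"] = bma

        stage = "stage1-evaluate"
        observed = test_followup.observations.rename(columns={"value": "observed"})
        marker_scores = []
        for name, ps in predictions.items():
            joined = ps.table.merge(observed, on=["subject_id", "time_years", "marker"], how="inner")
            widths = np.maximum((joined["hi"] - joined["lo"]).to_numpy(), 1e-9)
            mae = mean_absolute_error(joined["mean"], joined["observed"])
            wes = weighted_error_score(joined["mean"], joined["observed"], widths)
            marker_scores.append({"model": name, "MAE": mae.value, "WES": wes.value, "n": mae.n})
        marker_scores = pd.DataFrame(marker_scores)
        marker_scores.to_csv(out / "marker_scores.csv", index=False)
        report["marker_scores"] = marker_scores.to_dict(orient="records")

        stage = "stage2-train"
        train_features = build_feature_table(
            train, include_baseline_dx=config.stage2_include_baseline_dx
        )
        labelled = train_features[train_features["dx"].notna()].reset_index(drop=True)
        imputer = MissForestImputer(seed=config.seed)
        feature_cols = [c for c in labelled.columns if c not in ("subject_id", "dx")]
        completed = imputer.fit_transform(labelled[feature_cols])
        completed = pd.concat([labelled[["subject_id", "dx"]], completed], axis=1)
        forest = train_diagnosis_forest(completed, n_trees=config.stage2_n_trees, seed=config.seed)
        report["oob_error"] = forest.oob_error
        report["variable_importance"] = {k: float(v) for k, v in forest.importances.items()}
        log.info("[stage2-train] OOB error %.4f", forest.oob_error)

        stage = "stage2-predict"
        truth_dx = test_followup.diagnoses
        dx_results = {}
        for name, ps in predictions.items():
            feats = build_feature_table(
                test_followup,
                include_baseline_dx=config.stage2_include_baseline_dx,
                predictions=ps.table,
            )
            feats = feats.drop(columns=["dx"], errors="ignore")
            completed_cols = imputer.transform(feats[feature_cols])
            pred = predict_diagnosis(
                forest,
                pd.concat([feats[["subject_id"]], completed_cols], axis=1),
                return_votes=True,
            )
            pred.to_csv(out / f"diagnoses_{name}.csv", index=False)
            per_time = metrics_by_time(truth_dx, pred, config.eval_times)
            per_time.to_csv(out / f"dx_metrics_{name}.csv", index=False)
            agg = weighted_aggregate_bca(
                per_time["bca_overall"].to_numpy(), per_time["n"].to_numpy()
            )
            dx_results[name] = {
                "per_time": per_time.to_dict(orient="records"),
                "weighted_aggregate_bca": agg,
            }
            log.info("[stage2-predict] %s weighted aggregate BCA %.3f", name, agg)
        report["diagnosis_metrics"] = dx_results

        stage = "report"
        manifest = {
            "config_hash": report["config_hash"],
            "seed": config.seed,
            "families": list(config.families),
            "anchor_marker": config.anchor_marker,
            "test_subjects": list(map(str, test_ids)),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, default=float)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; last good artifacts in {out}"
        ) from exc
    return report


def evaluate_only(predictions_path, truth_path, grid=None) -> dict:
    """Recompute evaluation metrics from exported artifacts, without refitting.

    Marker-prediction CSVs (``subject_id,time_years,marker,mean,lo95,hi95``)
    joined against an observations CSV yield MAE and WES; diagnosis CSVs
    (``subject_id,time_years,dx_pred``) joined against a diagnoses CSV
    yield per-time accuracy and BCA.
    """
    pred = pd.read_csv(predictions_path)
    truth = pd.read_csv(truth_path)
    if "dx_pred" in pred.columns:
        if "dx" not in truth.columns:
            raise ValidationError("diagnosis truth CSV must have a 'dx' column")
        per_time = metrics_by_time(truth, pred, grid)
        agg = weighted_aggregate_bca(per_time["bca_overall"].to_numpy(), per_time["n"].to_numpy())
        return {
            "per_time": per_time.to_dict(orient="records"),
            "weighted_aggregate_bca": agg,
        }
    pred = pred.rename(columns={"lo95": "lo", "hi95": "hi"})
    value_col = "value" if "value" in truth.columns else "observed"
    joined = pred.merge(truth, on=["subject_id", "time_years", "marker"], how="inner")
    if grid is not None:
        joined = joined[joined["time_years"].isin(list(grid))]
    if len(joined) == 0:
        raise ValidationError("join of predictions and truth produced zero rows")
    widths = np.maximum((joined["hi"] - joined["lo"]).to_numpy(), 1e-9)
    mae = mean_absolute_error(joined["mean"], joined[value_col])
    wes = weighted_error_score(joined["mean"], joined[value_col], widths)
    return {"MAE": mae.value, "WES": wes.value, "n": mae.n}
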