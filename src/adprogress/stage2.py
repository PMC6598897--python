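"""Random-forest diagnostic staging from marker panels.

Given a panel of continuous markers per visit — observed at training time,
forecast by the longitudinal stage at prediction time — plus demographic
covariates, a 100-tree random forest classifies each (subject, time) row
into CN / MCI / Dementia.  Visits with incomplete marker panels are first
completed with an iterative random-forest imputer (the MissForest
procedure) so no visit has to be discarded.  Amyloid-status utilities
convert florbetapir PET SUVR and CSF A-beta-42 measures into a binary
elevated / not-elevated predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .data import DX_LABELS, LongitudinalDataset
from .errors import ConfigurationError, ValidationError

#: Default amyloid-elevation cutoffs: florbetapir PET SUVR strictly above
#: 1.10, or CSF A-beta-42 strictly below 909.6 pg/ml.
SUVR_CUT = 1.10
CSF_CUT = 909.6

_CATEGORICAL = ("sex", "apoe4", "marital", "dx_bl", "amyloid_status")


def build_feature_table(
    dataset: LongitudinalDataset,
    include_baseline_dx: bool = True,
    include_amyloid: bool = False,
    markers: list[str] | None = None,
    predictions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (subject, time): marker panel + covariates (+ label).

    With ``predictions`` (columns ``subject_id, time_years, marker, mean``)
    the marker columns come from forecasts instead of observations.  Age is
    supplied time-varying as baseline age + years from baseline.  The
    diagnosis label column ``dx`` is attached where a record exists.
    """
    markers = list(markers or dataset.marker_panel)
    if predictions is not None:
        wide = predictions.pivot_table(
            index=["subject_id", "time_years"], columns="marker", values="mean", aggfunc="first"
        ).reindex(columns=markers)
    else:
        wide = dataset.to_wide()[markers]
    table = wide.reset_index()
    cov_cols = ["subject_id", "age_bl", "sex", "apoe4", "educ_years", "marital"]
    if include_baseline_dx:
        cov_cols.append("dx_bl")
    cov = dataset.covariates[[c for c in cov_cols if c in dataset.covariates.columns]]
    table = table.merge(cov, on="subject_id", how="left")
    table["age"] = table["age_bl"] + table["time_years"]
    table = table.drop(columns=["age_bl"])
    if include_amyloid:
        amy = dataset.covariates[["subject_id", "amyloid_suvr", "amyloid_csf"]].copy()
        amy["amyloid_status"] = [
            classify_amyloid(s if pd.notna(s) else None, c if pd.notna(c) else None)
            if pd.notna(s) or pd.notna(c)
            else np.nan
            for s, c in zip(amy["amyloid_suvr"], amy["amyloid_csf"])
        ]
        table = table.merge(amy[["subject_id", "amyloid_status"]], on="subject_id", how="left")
    if len(dataset.diagnoses):
        table = table.merge(dataset.diagnoses, on=["subject_id", "time_years"], how="left")
    for col in _CATEGORICAL:
        if col in table.columns:
            table[col] = table[col].astype(object)
    return table


# ---------------------------------------------------------------------------
# MissForest-style iterative imputation


@dataclass
class MissForestImputer:
    """Iterative random-forest imputation for mixed-type feature tables.

    Missing continuous cells start at column means and categoricals at
    column modes; variables are then revisited in increasing-missingness
    order, each regressed on all others with a random forest whose
    predictions overwrite that variable's missing cells.  Iteration stops
    when the change statistic (sum of squared normalized differences for
    continuous variables, mismatch proportion for categoricals) first
    increases, returning the last-improving completion.  Observed cells
    are never altered.
    """

    max_iters: int = 10
    n_trees: int = 100
    seed: int = 0
    models_: dict = field(default_factory=dict, init=False)
    columns_: list = field(default_factory=list, init=False)
    init_stats_: dict = field(default_factory=dict, init=False)
    n_iterations_: int = 0

    def _is_categorical(self, s: pd.Series) -> bool:
        return not pd.api.types.is_numeric_dtype(s)

    def _encode(self, df: pd.DataFrame, target: str) -> np.ndarray:
        parts = []
        for col in df.columns:
            if col == target:
                continue
            if self._is_categorical(df[col]):
                dummies = pd.get_dummies(df[col].astype(str), prefix=col)
                parts.append(dummies.to_numpy(dtype=float))
            else:
                parts.append(df[[col]].to_numpy(dtype=float))
        return np.hstack(parts)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if len(table) < 2:
            raise ValidationError("imputation requires at least 2 rows")
        df = table.copy()
        self.columns_ = list(df.columns)
        fully_missing = [c for c in df.columns if df[c].isna().all()]
        if fully_missing:
            raise ValidationError(f"column(s) fully missing: {fully_missing}")

        miss_mask = df.isna()
        if not miss_mask.any().any():
            self.n_iterations_ = 0
            return df

        # initialization: column means / modes
        for col in df.columns:
            if not miss_mask[col].any():
                continue
            if self._is_categorical(df[col]):
                mode = df[col].mode(dropna=True).iloc[0]
                self.init_stats_[col] = mode
                df.loc[miss_mask[col], col] = mode
            else:
                mean = float(df[col].mean())
                self.init_stats_[col] = mean
                df.loc[miss_mask[col], col] = mean

        order = miss_mask.sum().sort_values(kind="stable")
        targets = [c for c in order.index if miss_mask[c].any()]
        rng = np.random.default_rng(self.seed)

        best = df.copy()
        prev_cont = prev_cat = np.inf
        for it in range(self.max_iters):
            models_this_iter = {}
            for col in targets:
                obs_rows = ~miss_mask[col]
                Xall = self._encode(df, col)
                if self._is_categorical(df[col]):
                    forest = RandomForestClassifier(
                        n_estimators=self.n_trees, random_state=int(rng.integers(2**31 - 1))
                    )
                    forest.fit(Xall[obs_rows.to_numpy()], df.loc[obs_rows, col].astype(str))
                    df.loc[miss_mask[col], col] = forest.predict(Xall[miss_mask[col].to_numpy()])
                else:
                    forest = RandomForestRegressor(
                        n_estimators=self.n_trees, random_state=int(rng.integers(2**31 - 1))
                    )
                    forest.fit(Xall[obs_rows.to_numpy()], df.loc[obs_rows, col].astype(float))
                    df.loc[miss_mask[col], col] = forest.predict(Xall[miss_mask[col].to_numpy()])
                models_this_iter[col] = forest

            # change statistics against the previous completion
            cont_num = cont_den = 0.0
            cat_mis = cat_tot = 0
            for col in targets:
                new = df.loc[miss_mask[col], col]
                old = best.loc[miss_mask[col], col]
                if self._is_categorical(df[col]):
                    cat_mis += int((new.astype(str) != old.astype(str)).sum())
                    cat_tot += len(new)
                else:
                    cont_num += float(((new.astype(float) - old.astype(float)) ** 2).sum())
                    cont_den += float((new.astype(float) ** 2).sum())
            d_cont = cont_num / cont_den if cont_den > 0 else 0.0
            d_cat = cat_mis / cat_tot if cat_tot > 0 else 0.0

            self.n_iterations_ = it + 1
            if it > 0 and (d_cont > prev_cont or d_cat > prev_cat):
                break  # degraded: keep last-improving completion
            best = df.copy()
            self.models_ = models_this_iter
            prev_cont, prev_cat = d_cont, d_cat

        # invariant: observed cells untouched
        for col in table.columns:
            obs = ~miss_mask[col]
            best.loc[obs, col] = table.loc[obs, col]
        return best

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Complete new rows using the frozen initialization and forests."""
        df = table.copy()
        if list(df.columns) != self.columns_:
            raise ValidationError("column schema differs from the fitted table")
        miss = df.isna()
        if not miss.any().any():
            return df
        for col in df.columns:
            if miss[col].any():
                fill = self.init_stats_.get(col)
                if fill is None:
                    fill = df[col].mode(dropna=True).iloc[0] if self._is_categorical(df[col]) else float(df[col].mean())
                df.loc[miss[col], col] = fill
        for col, forest in self.models_.items():
            if miss[col].any():
                Xall = self._encode(df, col)
                df.loc[miss[col], col] = forest.predict(Xall[miss[col].to_numpy()])
        return df


def impute_missing(table: pd.DataFrame, max_iters: int = 10, seed: int = 0) -> pd.DataFrame:
    """One-shot MissForest completion of a feature table."""
    return MissForestImputer(max_iters=max_iters, seed=seed).fit_transform(table)


# ---------------------------------------------------------------------------
# Diagnosis forest


_ID_COLUMNS = ("subject_id", "dx")


@dataclass
class ForestModel:
    """A fitted 100-tree diagnosis classifier with its training schema."""

    forest: RandomForestClassifier
    feature_columns: list[str]       # original (pre-encoding) feature names
    encoded_columns: list[str]
    categorical_levels: dict[str, list[str]]
    labels: tuple[str, ...]
    oob_error: float
    importances: pd.Series           # Gini importance per original feature

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators


def _encode_features(
    table: pd.DataFrame, feature_columns: list[str], levels: dict[str, list[str]]
) -> tuple[np.ndarray, list[str]]:
    parts, names = [], []
    for col in feature_columns:
        if col in levels:
            for lev in levels[col]:
                parts.append((table[col].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
        else:
            parts.append(table[col].to_numpy(dtype=float))
            names.append(col)
    return np.column_stack(parts), names


def train_diagnosis_forest(
    table: pd.DataFrame, n_trees: int = 100, seed: int = 0, label_column: str = "dx"
) -> ForestModel:
    """Fit the diagnosis random forest on a complete, labelled feature table.

    Bootstrap per tree, sqrt(feature count) candidate features per split,
    out-of-bag error from out-of-bootstrap votes, mean-decrease-in-Gini
    variable importances.
    """
    if table.isna().any().any():
        raise ValidationError("feature table has missing cells; impute first")
    labels = table[label_column]
    if labels.nunique() < 2:
        raise ValidationError("training labels contain a single class")
    feature_columns = [c for c in table.columns if c not in (*_ID_COLUMNS, label_column)]
    levels = {
        c: sorted(table[c].astype(str).unique())
        for c in feature_columns
        if not pd.api.types.is_numeric_dtype(table[c])
    }
    X, encoded = _encode_features(table, feature_columns, levels)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        bootstrap=True, random_state=seed,
    )
    forest.fit(X, labels.astype(str))
    imp_encoded = pd.Series(forest.feature_importances_, index=encoded)
    agg = {}
    for col in feature_columns:
        cols = [n for n in imp_encoded.index if n == col or n.startswith(f"{col}[")]
        agg[col] = float(imp_encoded[cols].sum())
    importances = pd.Series(agg).sort_values(ascending=False)
    present = tuple(lab for lab in DX_LABELS if lab in set(labels.astype(str)))
    return ForestModel(
        forest=forest,
        feature_columns=feature_columns,
        encoded_columns=encoded,
        categorical_levels=levels,
        labels=present or tuple(sorted(labels.astype(str).unique())),
        oob_error=float(1.0 - forest.oob_score_),
        importances=importances,
    )


def predict_diagnosis(
    model: ForestModel, table: pd.DataFrame, return_votes: bool = False
):
    """Majority-vote diagnosis per row; ties break toward the less severe class.

    Returns a DataFrame ``subject_id, time_years, dx_pred`` (plus per-class
    vote proportions when requested).  The table schema must match the
    training schema.
    """
    missing = [c for c in model.feature_columns if c not in table.columns]
    extra = [
        c for c in table.columns
        if c not in model.feature_columns and c not in (*_ID_COLUMNS, "time_years")
    ]
    if missing:
        raise ValidationError(f"feature table schema mismatch; missing {missing}, extra {extra}")
    sub = table[model.feature_columns]
    if sub.isna().any().any():
        raise ValidationError("prediction rows contain missing cells; impute first")
    X, _ = _encode_features(table, model.feature_columns, model.categorical_levels)
    proba = model.forest.predict_proba(X)
    classes = list(model.forest.classes_)
    severity_order = [lab for lab in DX_LABELS if lab in classes] + [
        c for c in classes if c not in DX_LABELS
    ]
    reord = [classes.index(lab) for lab in severity_order]
    proba_sev = proba[:, reord]
    pred = np.asarray(severity_order)[np.argmax(proba_sev, axis=1)]  # argmax ties -> less severe
    out = pd.DataFrame(
        {
            "subject_id": table.get("subject_id", pd.Series(range(len(table)))).to_numpy(),
            "time_years": table.get("time_years", pd.Series(np.zeros(len(table)))).to_numpy(),
            "dx_pred": pred,
        }
    )
    if return_votes:
        for lab in severity_order:
            out[f"p_{lab}"] = proba_sev[:, severity_order.index(lab)]
    return out


def variable_importance(model: ForestModel) -> pd.Series:
    """Descending mean-decrease-in-Gini importance per original feature."""
    imp = model.importances
    if (imp < 0).any():
        raise ValidationError("importances must be non-negative")
    return imp.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Amyloid utilities


def classify_amyloid(
    suvr: float | None = None,
    csf: float | None = None,
    suvr_cut: float = SUVR_CUT,
    csf_cut: float = CSF_CUT,
) -> str:
    """Elevated iff SUVR > suvr_cut or CSF < csf_cut (strict inequalities).

    Either modality may establish elevation when both are present.
    """
    if suvr is None and csf is None:
        raise ValidationError("at least one amyloid measure is required")
    elevated = (suvr is not None and suvr > suvr_cut) or (csf is not None and csf < csf_cut)
    return "elevated" if elevated else "not-elevated"


def derive_csf_cutoff(suvr_values, csf_values, suvr_cut: float = SUVR_CUT) -> float:
    """CSF threshold yielding the same positive fraction as the SUVR cutoff.

    Returns the csf sample value c such that fraction{csf < c} is as close
    as achievable to fraction{suvr > suvr_cut}; ties break toward the
    lower quantile.
    """
    suvr = np.asarray(suvr_values, dtype=float)
    csf = np.sort(np.asarray(csf_values, dtype=float))
    if len(suvr) == 0 or len(csf) == 0:
        raise ValidationError("both amyloid samples must be non-empty")
    target = float(np.mean(suvr > suvr_cut))
    n = len(csf)
    ks = np.arange(n + 1)
    err = np.abs(ks / n - target)
    k = int(ks[np.argmin(err)])  # argmin takes the first (lower) on ties
    if k >= n:
        return float(np.nextafter(csf[-1], np.inf))
    return float(csf[k])
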