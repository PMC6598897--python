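"""Model-ready design arrays from a percentile-scale dataset.

Row order is deterministic: (subject, time, marker-panel position).
Categorical covariates are reference-coded with fixed category orders;
continuous covariates enter unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..data import DX_LABELS, LongitudinalDataset
from ..errors import ConfigurationError
from .spec import ModelSpec

# fixed reference-coding orders (first level is the reference)
_CATEGORY_ORDERS = {
    "sex": ["female", "male"],
    "apoe4": ["non-carrier", "carrier"],
    "dx_bl": list(DX_LABELS),
    "amyloid_status": ["not-elevated", "elevated"],
}
_CONTINUOUS = {"age_bl", "educ_years"}


@dataclass
class Design:
    """Flat per-observation arrays plus per-subject covariate rows."""

    y: np.ndarray            # response on the percentile scale, (N,)
    t: np.ndarray            # years from baseline, (N,)
    subj_idx: np.ndarray     # 0-based subject index, (N,)
    marker_idx: np.ndarray   # 0-based marker index into `markers`, (N,)
    X: np.ndarray            # covariate rows incl. intercept, (N, d)
    x_cols: list[str]
    subjects: list[str]
    markers: list[str]
    subject_X: np.ndarray    # one covariate row per subject, (n, d)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def key_frame(self) -> pd.DataFrame:
        """(subject_id, time_years, marker) identity of each design row."""
        return pd.DataFrame(
            {
                "subject_id": np.asarray(self.subjects)[self.subj_idx],
                "time_years": self.t,
                "marker": np.asarray(self.markers)[self.marker_idx],
            }
        )


def _encode_covariates(cov: pd.DataFrame, names: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(cov))]
    labels: list[str] = ["intercept"]
    for name in names:
        if name not in cov.columns:
            raise ConfigurationError(f"covariate {name!r} absent from covariate profiles")
        series = cov[name]
        if series.isna().any():
            raise ConfigurationError(f"covariate {name!r} has missing values for some subjects")
        if name in _CONTINUOUS or pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            labels.append(name)
        else:
            order = _CATEGORY_ORDERS.get(name)
            if order is None:
                order = sorted(series.astype(str).unique())
            unknown = set(series.astype(str)) - set(order)
            if unknown:
                raise ConfigurationError(f"covariate {name!r} has unknown levels {sorted(unknown)}")
            for level in order[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                labels.append(f"{name}[{level}]")
    return np.column_stack(cols), labels


def build_design(dataset: LongitudinalDataset, spec: ModelSpec) -> Design:
    """Assemble design arrays for one model family.

    The dataset is expected to hold percentile-scale responses already
    (see :func:`adprogress.transform.dataset_to_percentiles`).
    """
    markers = list(spec.markers)
    missing = set(markers) - set(dataset.marker_panel)
    if missing:
        raise ConfigurationError(f"spec markers not in dataset panel: {sorted(missing)}")

    obs = dataset.observations[dataset.observations["marker"].isin(markers)].copy()
    marker_pos = {m: k for k, m in enumerate(markers)}
    obs["_k"] = obs["marker"].map(marker_pos)
    obs = obs.sort_values(["subject_id", "time_years", "_k"], kind="stable").reset_index(drop=True)

    subjects = sorted(obs["subject_id"].unique())
    subj_pos = {s: i for i, s in enumerate(subjects)}

    cov = dataset.covariates.set_index("subject_id").loc[subjects].reset_index()
    subject_X, x_cols = _encode_covariates(cov, spec.covariates)

    subj_idx = obs["subject_id"].map(subj_pos).to_numpy(dtype=np.int64)
    return Design(
        y=obs["value"].to_numpy(dtype=float),
        t=obs["time_years"].to_numpy(dtype=float),
        subj_idx=subj_idx,
        marker_idx=obs["_k"].to_numpy(dtype=np.int64),
        X=subject_X[subj_idx],
        x_cols=x_cols,
        subjects=subjects,
        markers=markers,
        subject_X=subject_X,
    )
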