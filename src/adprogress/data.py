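"""Long-format longitudinal data model and dataset-construction rules.

The canonical container is :class:`LongitudinalDataset`: one row per
subject x visit x marker observation (long format), a per-subject covariate
table, and per-visit diagnosis records.  Missing marker values are encoded
as absent rows, never as sentinel values.  Time is measured in years from
each subject's baseline visit, where "baseline" means the subject's minimum
observed time (robust to registration jitter; equals t = 0 on synthetic
cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

#: The three diagnostic classes, ordered by severity.
DX_LABELS = ("CN", "MCI", "Dementia")

OBS_COLUMNS = ["subject_id", "time_years", "marker", "value"]
COV_COLUMNS = [
    "subject_id",
    "age_bl",
    "sex",
    "apoe4",
    "educ_years",
    "marital",
    "dx_bl",
    "amyloid_suvr",
    "amyloid_csf",
]
#: Covariate columns that may be absent from an input file.
COV_OPTIONAL = ["amyloid_suvr", "amyloid_csf", "dx_bl", "marital", "educ_years"]
DX_COLUMNS = ["subject_id", "time_years", "dx"]


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


@dataclass
class LongitudinalDataset:
    """Observations, covariates and diagnoses for one cohort.

    Parameters
    ----------
    observations
        Long table with columns ``subject_id, time_years, marker, value``.
        Rows with a missing ``value`` are dropped (absence encodes
        missingness).
    covariates
        One row per subject: ``subject_id, age_bl, sex, apoe4, educ_years,
        marital, dx_bl`` plus optional amyloid measures.
    diagnoses
        Per-visit diagnosis records ``subject_id, time_years, dx`` with
        ``dx`` in ``{"CN", "MCI", "Dementia"}``.
    marker_panel
        Ordered list of marker names defining the outcome index
        k = 1..p.  Defaults to the sorted set of observed markers.
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame
    diagnoses: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DX_COLUMNS))
    marker_panel: list[str] | None = None

    def __post_init__(self) -> None:
        obs = self.observations.copy()
        _require_columns(obs, OBS_COLUMNS, "observations")
        obs = obs[OBS_COLUMNS]
        obs["subject_id"] = obs["subject_id"].astype(str)
        obs["time_years"] = pd.to_numeric(obs["time_years"], errors="raise")
        obs["marker"] = obs["marker"].astype(str)
        obs["value"] = pd.to_numeric(obs["value"], errors="raise")
        obs = obs.dropna(subset=["value"]).reset_index(drop=True)
        if (obs["time_years"] < 0).any():
            bad = obs.loc[obs["time_years"] < 0].iloc[0]
            raise ValidationError(
                f"negative time {bad['time_years']} for subject {bad['subject_id']}"
            )
        if not np.isfinite(obs["time_years"]).all():
            raise ValidationError("non-finite time_years in observations")
        dup = obs.duplicated(subset=["subject_id", "time_years", "marker"], keep=False)
        if dup.any():
            key = obs.loc[dup, ["subject_id", "time_years", "marker"]].iloc[0]
            raise ValidationError(
                "duplicate observation for (subject_id, time_years, marker)="
                f"({key['subject_id']}, {key['time_years']}, {key['marker']})"
            )

        cov = self.covariates.copy()
        _require_columns(cov, ["subject_id"], "covariates")
        cov["subject_id"] = cov["subject_id"].astype(str)
        for col in COV_COLUMNS:
            if col not in cov.columns:
                cov[col] = np.nan
        cov = cov[COV_COLUMNS]
        if cov["subject_id"].duplicated().any():
            sid = cov.loc[cov["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"more than one covariate profile for subject {sid}")

        dx = self.diagnoses.copy()
        if len(dx) == 0:
            dx = pd.DataFrame(columns=DX_COLUMNS)
        _require_columns(dx, DX_COLUMNS, "diagnoses")
        dx = dx[DX_COLUMNS]
        dx["subject_id"] = dx["subject_id"].astype(str)
        if len(dx):
            dx["time_years"] = pd.to_numeric(dx["time_years"], errors="raise")
            bad_dx = ~dx["dx"].isin(DX_LABELS)
            if bad_dx.any():
                raise ValidationError(
                    f"unknown diagnosis label {dx.loc[bad_dx, 'dx'].iloc[0]!r}; "
                    f"expected one of {DX_LABELS}"
                )
            if (dx["time_years"] < 0).any():
                raise ValidationError("negative time_years in diagnoses")

        missing_profiles = set(obs["subject_id"]) - set(cov["subject_id"])
        if missing_profiles:
            raise ValidationError(
                f"subjects without a covariate profile: {sorted(missing_profiles)[:5]}"
            )

        if self.marker_panel is None:
            panel = sorted(obs["marker"].unique())
        else:
            panel = list(self.marker_panel)
        if len(panel) != len(set(panel)):
            raise ValidationError("marker_panel contains duplicates")
        unknown = set(obs["marker"]) - set(panel)
        if unknown:
            raise ValidationError(f"observations contain markers not in panel: {sorted(unknown)}")

        self.observations = obs
        self.covariates = cov.reset_index(drop=True)
        self.diagnoses = dx.reset_index(drop=True)
        self.marker_panel = panel

    # -- views ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return sorted(self.observations["subject_id"].unique())

    def baseline_times(self) -> pd.Series:
        """Minimum observed time per subject (the baseline visit)."""
        return self.observations.groupby("subject_id")["time_years"].min()

    def n_rows(self) -> int:
        return len(self.observations)

    def to_wide(self) -> pd.DataFrame:
        """Wide (subject, time) x marker pivot view; missing cells are NaN."""
        wide = self.observations.pivot_table(
            index=["subject_id", "time_years"],
            columns="marker",
            values="value",
            aggfunc="first",
        )
        return wide.reindex(columns=self.marker_panel)

    def equals(self, other: "LongitudinalDataset") -> bool:
        def _sorted(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return df.sort_values(keys).reset_index(drop=True)

        return (
            _sorted(self.observations, OBS_COLUMNS[:3]).equals(
                _sorted(other.observations, OBS_COLUMNS[:3])
            )
            and _sorted(self.covariates, ["subject_id"]).equals(
                _sorted(other.covariates, ["subject_id"])
            )
            and _sorted(self.diagnoses, DX_COLUMNS[:2]).equals(
                _sorted(other.diagnoses, DX_COLUMNS[:2])
            )
            and self.marker_panel == other.marker_panel
        )


# ---------------------------------------------------------------------------
# I/O


def read_long_table(
    observations_path,
    covariates_path,
    diagnoses_path=None,
    marker_panel: list[str] | None = None,
) -> LongitudinalDataset:
    """Read the three canonical CSV files into a validated dataset.

    Headers are required; times must parse as non-negative reals; duplicate
    (subject, time, marker) rows are rejected.
    """
    obs = pd.read_csv(observations_path, float_precision="round_trip")
    cov = pd.read_csv(covariates_path, float_precision="round_trip")
    if diagnoses_path is not None:
        dx = pd.read_csv(diagnoses_path, float_precision="round_trip")
    else:
        dx = pd.DataFrame(columns=DX_COLUMNS)
    return LongitudinalDataset(obs, cov, dx, marker_panel=marker_panel)


def write_long_table(dataset: LongitudinalDataset, observations_path, covariates_path, diagnoses_path) -> None:
    """Write the dataset back to the three canonical CSV files."""
    dataset.observations.to_csv(observations_path, index=False)
    dataset.covariates.to_csv(covariates_path, index=False)
    dataset.diagnoses.to_csv(diagnoses_path, index=False)


# ---------------------------------------------------------------------------
# Dataset-construction rules


def filter_visits_missing_anchor(dataset: LongitudinalDataset, anchor_marker: str) -> LongitudinalDataset:
    """Drop every (subject, visit) at which the anchor marker was not observed.

    Enforces a minimum standard of visit completion: a visit enters the
    analysis set only if the anchor assessment (CDRSB in the reference
    configuration) has an observed value there.  All markers at dropped
    visits are removed; covariates and diagnoses are untouched.  Idempotent.
    """
    if anchor_marker not in dataset.marker_panel:
        raise ConfigurationError(f"anchor marker {anchor_marker!r} is not in the marker panel")
    obs = dataset.observations
    anchored = obs.loc[obs["marker"] == anchor_marker, ["subject_id", "time_years"]]
    keep = obs.merge(anchored, on=["subject_id", "time_years"], how="inner")
    return replace(dataset, observations=keep, marker_panel=list(dataset.marker_panel))


def build_training_split(
    dataset: LongitudinalDataset, test_subject_ids
) -> tuple[LongitudinalDataset, LongitudinalDataset]:
    """Split into training data and held-out test follow-up.

    The training set contains all rows of non-test subjects *plus the
    baseline visit of every test subject*, so that test subjects' random
    effects can be estimated at fit time; the test set contains only their
    follow-up (non-baseline) visits.  The two parts partition the
    observation rows exactly.
    """
    test_ids = {str(s) for s in test_subject_ids}
    unknown = test_ids - set(dataset.subjects)
    if unknown:
        raise ValidationError(f"test subjects not present in dataset: {sorted(unknown)[:5]}")

    obs = dataset.observations
    base = dataset.baseline_times()
    is_test = obs["subject_id"].isin(test_ids)
    at_baseline = obs["time_years"].to_numpy() == base.reindex(obs["subject_id"]).to_numpy()
    train_mask = (~is_test) | at_baseline

    lone = [
        sid
        for sid in sorted(test_ids)
        if (obs.loc[obs["subject_id"] == sid, "time_years"] == base[sid]).all()
    ]
    if lone:
        warnings.warn(
            f"test subjects with only a baseline visit stay in training only: {lone}",
            stacklevel=2,
        )

    dx = dataset.diagnoses
    if len(dx):
        dx_is_test = dx["subject_id"].isin(test_ids)
        dx_at_base = dx["time_years"].to_numpy() == base.reindex(dx["subject_id"]).to_numpy()
        dx_train_mask = (~dx_is_test) | dx_at_base
    else:
        dx_train_mask = np.zeros(0, dtype=bool)

    cov = dataset.covariates
    panel = list(dataset.marker_panel)
    train = LongitudinalDataset(obs[train_mask], cov, dx[dx_train_mask] if len(dx) else dx, marker_panel=panel)
    test = LongitudinalDataset(
        obs[~train_mask],
        cov[cov["subject_id"].isin(test_ids)],
        dx[~dx_train_mask] if len(dx) else dx,
        marker_panel=panel,
    )
    return train, test
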