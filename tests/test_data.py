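import numpy as np
import pandas as pd
import pytest

from adprogress.cohort import CohortConfig, apply_missingness, assign_diagnoses, generate_cohort
from adprogress.data import (
    LongitudinalDataset,
    build_training_split,
    filter_visits_missing_anchor,
    read_long_table,
    write_long_table,
)
from adprogress.errors import ConfigurationError, SchemaError, ValidationError


def _write_csvs(tmp_path, obs, cov, dx):
    obs.to_csv(tmp_path / "obs.csv", index=False)
    cov.to_csv(tmp_path / "cov.csv", index=False)
    dx.to_csv(tmp_path / "dx.csv", index=False)
    return tmp_path / "obs.csv", tmp_path / "cov.csv", tmp_path / "dx.csv"


class TestReadWrite:
    def test_three_row_toy_parse(self, tmp_path):
        obs = pd.DataFrame(
            {"subject_id": ["s1"] * 3, "time_years": [0.0] * 3,
             "marker": ["a", "b", "c"], "value": [1, 2, 3]}
        )
        cov = pd.DataFrame({"subject_id": ["s1"], "age_bl": [70], "sex": ["male"], "apoe4": ["carrier"]})
        dx = pd.DataFrame({"subject_id": ["s1"], "time_years": [0.0], "dx": ["CN"]})
        ds = read_long_table(*_write_csvs(tmp_path, obs, cov, dx))
        assert ds.subjects == ["s1"]
        assert len(ds.marker_panel) == 3

    def test_duplicate_key_rejected_with_offender_named(self):
        obs = pd.DataFrame(
            {"subject_id": ["s1", "s1"], "time_years": [0.0, 0.0], "marker": ["a", "a"],
             "value": [1, 2]}
        )
        cov = pd.DataFrame({"subject_id": ["s1"]})
        with pytest.raises(ValidationError, match=r"s1.*a"):
            LongitudinalDataset(obs, cov)

    def test_negative_time_rejected(self):
        obs = pd.DataFrame({"subject_id": ["s1"], "time_years": [-0.5], "marker": ["a"], "value": [1]})
        with pytest.raises(ValidationError, match="negative"):
            LongitudinalDataset(obs, pd.DataFrame({"subject_id": ["s1"]}))

    def test_unknown_diagnosis_label_rejected(self):
        obs = pd.DataFrame({"subject_id": ["s1"], "time_years": [0.0], "marker": ["a"], "value": [1]})
        dx = pd.DataFrame({"subject_id": ["s1"], "time_years": [0.0], "dx": ["AD"]})
        with pytest.raises(ValidationError, match="AD"):
            LongitudinalDataset(obs, pd.DataFrame({"subject_id": ["s1"]}), dx)

    def test_missing_column_names_column(self, tmp_path):
        obs = pd.DataFrame({"subject_id": ["s1"], "time_years": [0.0], "value": [1]})
        with pytest.raises(SchemaError, match="marker"):
            LongitudinalDataset(obs, pd.DataFrame({"subject_id": ["s1"]}))

    def test_round_trip_identity(self, tmp_path):
        cfg = CohortConfig(n_subjects=8, markers=("ADAS13", "CDRSB"), seed=4,
                           mcar_rate=0.1, dropout_hazard=0.2)
        ds, truth = generate_cohort(cfg)
        ds = assign_diagnoses(ds, truth)
        paths = (tmp_path / "o.csv", tmp_path / "c.csv", tmp_path / "d.csv")
        write_long_table(ds, *paths)
        back = read_long_table(*paths, marker_panel=ds.marker_panel)
        assert back.equals(ds)

    def test_subject_without_profile_rejected(self):
        obs = pd.DataFrame({"subject_id": ["s1"], "time_years": [0.0], "marker": ["a"], "value": [1]})
        with pytest.raises(ValidationError, match="profile"):
            LongitudinalDataset(obs, pd.DataFrame({"subject_id": ["s2"]}))


class TestAnchorFilter:
    def test_all_visits_anchored_is_identity(self, toy_dataset):
        ds = filter_visits_missing_anchor(toy_dataset, "m1")
        assert ds.equals(toy_dataset)

    def test_visit_without_anchor_dropped_entirely(self, toy_dataset):
        ds = filter_visits_missing_anchor(toy_dataset, "m0")
        assert set(ds.observations["time_years"]) == {0.0}
        assert len(ds.observations) == 3
        # covariates untouched
        assert ds.covariates.equals(toy_dataset.covariates)

    def test_idempotent(self, toy_dataset):
        once = filter_visits_missing_anchor(toy_dataset, "m0")
        twice = filter_visits_missing_anchor(once, "m0")
        assert twice.equals(once)

    def test_unknown_anchor_is_configuration_error(self, toy_dataset):
        with pytest.raises(ConfigurationError):
            filter_visits_missing_anchor(toy_dataset, "nope")

    def test_retained_visits_match_enumeration_under_mcar(self):
        cfg = CohortConfig(n_subjects=40, markers=("ADAS13", "CDRSB", "MMSE"),
                           mcar_rate=0.2, dropout_hazard=0.0, seed=9)
        ds, truth = generate_cohort(cfg)
        ds = apply_missingness(ds, config=cfg)
        filtered = filter_visits_missing_anchor(ds, "CDRSB")
        # brute-force enumeration: visits where the anchor is present
        obs = ds.observations
        anchored = {
            (s, t)
            for s, t, m in zip(obs["subject_id"], obs["time_years"], obs["marker"])
            if m == "CDRSB"
        }
        expected_rows = sum(
            (s, t) in anchored
            for s, t in zip(obs["subject_id"], obs["time_years"])
        )
        assert len(filtered.observations) == expected_rows
        kept_visits = set(zip(filtered.observations["subject_id"], filtered.observations["time_years"]))
        assert kept_visits == {v for v in anchored if v in kept_visits}  # never drops anchored visits
        assert anchored == kept_visits


class TestTrainingSplit:
    def test_empty_test_set_is_identity(self, toy_dataset):
        train, test = build_training_split(toy_dataset, [])
        assert train.equals(toy_dataset)
        assert test.n_rows() == 0

    def test_baseline_goes_to_train_followups_to_test(self):
        obs = pd.DataFrame(
            {"subject_id": ["s1"] * 3, "time_years": [0.0, 1.0, 2.0],
             "marker": ["a"] * 3, "value": [1.0, 2.0, 3.0]}
        )
        ds = LongitudinalDataset(obs, pd.DataFrame({"subject_id": ["s1"]}))
        train, test = build_training_split(ds, ["s1"])
        assert train.observations["time_years"].tolist() == [0.0]
        assert sorted(test.observations["time_years"]) == [1.0, 2.0]

    def test_partition_property_on_synthetic_cohort(self):
        cfg = CohortConfig(n_subjects=50, markers=("ADAS13", "CDRSB"), seed=2,
                           mcar_rate=0.1, dropout_hazard=0.15)
        ds, truth = generate_cohort(cfg)
        ds = apply_missingness(ds, config=cfg)
        rng = np.random.default_rng(0)
        test_ids = rng.choice(ds.subjects, size=15, replace=False).tolist()
        train, test = build_training_split(ds, test_ids)
        assert train.n_rows() + test.n_rows() == ds.n_rows()
        # multiset equality of rows (partition: nothing lost or duplicated)
        key = ["subject_id", "time_years", "marker", "value"]
        combined = (
            pd.concat([train.observations, test.observations])[key]
            .sort_values(key).reset_index(drop=True)
        )
        assert combined.equals(ds.observations[key].sort_values(key).reset_index(drop=True))

    def test_baseline_only_test_subject_warns_not_errors(self):
        obs = pd.DataFrame(
            {"subject_id": ["s1", "s2", "s2"], "time_years": [0.0, 0.0, 1.0],
             "marker": ["a"] * 3, "value": [1.0, 2.0, 3.0]}
        )
        ds = LongitudinalDataset(obs, pd.DataFrame({"subject_id": ["s1", "s2"]}))
        with pytest.warns(UserWarning, match="baseline"):
            train, test = build_training_split(ds, ["s1"])
        assert "s1" in train.subjects
        assert test.n_rows() == 0

    def test_unknown_test_subject_rejected(self, toy_dataset):
        with pytest.raises(ValidationError):
            build_training_split(toy_dataset, ["ghost"])
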