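import numpy as np
import pandas as pd
import pytest

from adprogress.errors import ValidationError
from adprogress.stage2 import (
    MissForestImputer,
    classify_amyloid,
    derive_csf_cutoff,
    impute_missing,
    predict_diagnosis,
    train_diagnosis_forest,
    variable_importance,
)


def separable_table(n=300, seed=0, noise_feature=False):
    """Diagnosis fully determined by thresholding one feature."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    dx = np.select([x < 1 / 3, x < 2 / 3], ["CN", "MCI"], "Dementia")
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "time_years": rng.choice([0.0, 1.0, 2.0], size=n),
            "anchor": x,
            "other": rng.normal(size=n),
            "sex": rng.choice(["female", "male"], size=n).astype(object),
            "dx": dx,
        }
    )
    if noise_feature:
        table["pure_noise"] = rng.normal(size=n)
        table = table[["subject_id", "time_years", "anchor", "other", "pure_noise", "sex", "dx"]]
    return table


class TestMissForest:
    def test_complete_table_returned_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": ["x", "y", "x"]})
        out = impute_missing(df, seed=0)
        assert out.equals(df)

    def test_initialization_uses_column_mean(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, 5.0], "b": [0.1, 0.2, 0.3, 0.4]})
        imp = MissForestImputer(seed=0)
        imp.fit_transform(df)
        assert imp.init_stats_["a"] == pytest.approx(np.mean([1.0, 2.0, 5.0]))

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        masked = df.copy()
        miss = rng.uniform(size=50) < 0.3
        masked.loc[miss, "b"] = np.nan
        out = impute_missing(masked, seed=1)
        assert np.array_equal(out.loc[~miss, "b"], df.loc[~miss, "b"])
        assert out["a"].equals(df["a"]) and out["c"].equals(df["c"])
        assert out["b"].notna().all()

    def test_beats_mean_imputation_on_correlated_columns(self):
        rng = np.random.default_rng(2)
        n = 150
        base = rng.normal(size=n)
        truth = pd.DataFrame(
            {
                "x1": base + 0.1 * rng.normal(size=n),
                "x2": base + 0.1 * rng.normal(size=n),
                "x3": -base + 0.1 * rng.normal(size=n),
            }
        )
        masked = truth.copy()
        miss = rng.uniform(size=n) < 0.2
        masked.loc[miss, "x2"] = np.nan
        out = impute_missing(masked, seed=2)
        rmse_forest = np.sqrt(np.mean((out.loc[miss, "x2"] - truth.loc[miss, "x2"]) ** 2))
        rmse_mean = np.sqrt(
            np.mean((masked["x2"].mean() - truth.loc[miss, "x2"]) ** 2)
        )
        assert rmse_forest < rmse_mean

    def test_mixed_type_imputation_fills_categoricals(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        cat = np.where(x > 0, "hi", "lo").astype(object)
        df = pd.DataFrame({"x": x, "cat": cat})
        miss = rng.uniform(size=n) < 0.25
        df.loc[miss, "cat"] = np.nan
        out = impute_missing(df, seed=3)
        assert out["cat"].notna().all()
        # a forest on a strongly predictive column should beat the mode
        acc = (out.loc[miss, "cat"] == pd.Series(cat)[miss]).mean()
        assert acc > 0.7

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValidationError, match="b"):
            impute_missing(df)


class TestDiagnosisForest:
    def test_default_forest_has_100_trees(self):
        model = train_diagnosis_forest(separable_table())
        assert model.n_trees == 100

    def test_separable_table_low_oob_error(self):
        model = train_diagnosis_forest(separable_table(n=300, seed=4), seed=4)
        assert model.oob_error < 0.05

    def test_separating_feature_ranks_first(self):
        model = train_diagnosis_forest(separable_table(seed=5), seed=5)
        assert variable_importance(model).index[0] == "anchor"

    def test_pure_noise_feature_ranks_last_among_informative(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.uniform(0, 1, n)
        table = pd.DataFrame(
            {
                "anchor": x,
                "correlate": x + 0.05 * rng.normal(size=n),
                "pure_noise": rng.normal(size=n),
                "dx": np.select([x < 1 / 3, x < 2 / 3], ["CN", "MCI"], "Dementia"),
            }
        )
        model = train_diagnosis_forest(table, seed=6)
        ranked = variable_importance(model)
        assert ranked.index[-1] == "pure_noise"
        assert (ranked >= 0).all()

    def test_training_rows_reproduced_and_votes_normalized(self):
        table = separable_table(n=200, seed=7)
        model = train_diagnosis_forest(table, seed=7)
        pred = predict_diagnosis(model, table.drop(columns=["dx"]), return_votes=True)
        assert (pred["dx_pred"].to_numpy() == table["dx"].to_numpy()).all()
        votes = pred[["p_CN", "p_MCI", "p_Dementia"]].to_numpy()
        assert np.allclose(votes.sum(axis=1), 1.0)

    def test_prediction_invariant_to_row_order(self):
        table = separable_table(n=120, seed=8)
        model = train_diagnosis_forest(table, seed=8)
        feats = table.drop(columns=["dx"])
        shuffled = feats.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = predict_diagnosis(model, feats).set_index("subject_id")["dx_pred"]
        b = predict_diagnosis(model, shuffled).set_index("subject_id")["dx_pred"]
        assert a.sort_index().equals(b.sort_index())

    def test_single_class_labels_rejected(self):
        table = separable_table(n=50, seed=9)
        table["dx"] = "CN"
        with pytest.raises(ValidationError):
            train_diagnosis_forest(table)

    def test_schema_mismatch_rejected(self):
        model = train_diagnosis_forest(separable_table(seed=10), seed=10)
        bad = separable_table(seed=10).drop(columns=["dx", "anchor"])
        with pytest.raises(ValidationError, match="anchor"):
            predict_diagnosis(model, bad)


class TestAmyloid:
    @pytest.mark.parametrize(
        "suvr,csf,expected",
        [
            (1.11, None, "elevated"),          # strictly above the SUVR cutoff
            (1.10, None, "not-elevated"),      # boundary: strict inequality
            (None, 909.6, "not-elevated"),     # boundary: strict 'less than'
            (None, 909.5, "elevated"),
            (1.05, 800.0, "elevated"),         # either modality suffices
            (1.05, 1000.0, "not-elevated"),
        ],
    )
    def test_classification_rule(self, suvr, csf, expected):
        assert classify_amyloid(suvr, csf) == expected

    def test_both_absent_rejected(self):
        with pytest.raises(ValidationError):
            classify_amyloid(None, None)

    def test_cutoff_hand_example(self):
        # half the SUVR sample is positive; csf {1,2,3,4} -> c = 3 gives 2/4 below
        suvr = [1.0, 1.0, 1.2, 1.2]
        assert derive_csf_cutoff(suvr, [1.0, 2.0, 3.0, 4.0]) == 3.0

    def test_no_positives_gives_cutoff_at_or_below_min(self):
        c = derive_csf_cutoff([1.0, 1.05], [500.0, 700.0, 900.0])
        assert c <= 500.0

    def test_matches_brute_force_scan_and_granularity_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            suvr = rng.normal(1.1, 0.15, size=rng.integers(5, 60))
            csf = rng.normal(900, 200, size=rng.integers(5, 60))
            target = np.mean(suvr > 1.10)
            c = derive_csf_cutoff(suvr, csf)
            achieved = np.mean(csf < c)
            # brute force: no candidate threshold does strictly better
            candidates = np.concatenate([csf, [csf.max() + 1.0]])
            best = min(abs(np.mean(csf < x) - target) for x in candidates)
            assert abs(achieved - target) <= best + 1e-12
            assert abs(achieved - target) <= 1.0 / len(csf) + 1e-12

    def test_classification_consistent_with_derived_cutoff(self):
        rng = np.random.default_rng(12)
        suvr = rng.normal(1.1, 0.2, size=40)
        csf = rng.normal(900, 150, size=50)
        c = derive_csf_cutoff(suvr, csf)
        labels = [classify_amyloid(None, x, csf_cut=c) for x in csf]
        frac = np.mean([lab == "elevated" for lab in labels])
        assert abs(frac - np.mean(suvr > 1.10)) <= 1.0 / len(csf) + 1e-12
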