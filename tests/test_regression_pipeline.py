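"""Cohort cleaning, imputation, selection, logistic ORs, multiplicity, VIF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kglink.ontology import Ontology, Term
from kglink.ontology_mapping import ResponseRecord, ResponseType, KeyEntry, TranslationKey
from kglink.regression_pipeline import (
    CohortError,
    FeatureTable,
    bonferroni_adjust,
    clean_cohort,
    compute_vif,
    fit_logistic,
    impute_missforest,
    results_frame,
    select_features,
    TABLE_COLUMNS,
)


def _mini_ontology():
    onto = Ontology()
    onto.add(Term("MONDO:1", "endometriosis", "disease"))
    for i in range(6):
        onto.add(Term(f"HP:{i}", f"phenotype {i}", "phenotype"))
    return onto


def _mini_key():
    key = TranslationKey()
    key.entries["qd"] = KeyEntry("qd", ResponseType.binary, "has_disease",
                                 curie="MONDO:1")
    for i in range(6):
        key.entries[f"q{i}"] = KeyEntry(f"q{i}", ResponseType.binary,
                                        "has_phenotype", curie=f"HP:{i}")
    return key


def _respondents(rows):
    return pd.DataFrame(rows, columns=["respondent_id", "sex", "completed_health",
                                       "completed_internal", "completed_external"])


class TestCleanCohort:
    def test_female_complete_filter_is_hand_countable(self):
        rows = []
        for i in range(10):
            sex = "female" if i < 6 else "male"
            complete = i in (0, 1, 2, 3)   # 4 of the 6 females complete all three
            rows.append((f"P{i}", sex, True, complete, complete))
        respondents = _respondents(rows)
        responses = [ResponseRecord(f"P{i}", "health", "qd", "No") for i in range(10)]
        responses += [ResponseRecord(f"P{i}", "health", "q0", "Yes") for i in range(10)]
        responses += [ResponseRecord("P0", "health", "qd", "Yes")]
        table = clean_cohort(respondents, responses, _mini_key(),
                             _mini_ontology(), ["MONDO:1"])
        assert table.n == 4
        assert set(table.outcomes.columns) == {"MONDO:1"}

    def test_respondent_missing_a_survey_is_excluded(self):
        respondents = _respondents([("P0", "female", True, True, False),
                                    ("P1", "female", True, True, True)])
        responses = [ResponseRecord(p, "health", q, "No")
                     for p in ("P0", "P1") for q in ("qd", "q0")]
        table = clean_cohort(respondents, responses, _mini_key(),
                             _mini_ontology(), ["MONDO:1"])
        assert list(table.features.index) == ["P1"]

    def test_all_male_input_raises_named_filter_error(self):
        respondents = _respondents([("P0", "male", True, True, True)])
        with pytest.raises(CohortError, match="female"):
            clean_cohort(respondents, [], _mini_key(), _mini_ontology(), ["MONDO:1"])

    def test_ordinal_values_kept_at_full_resolution(self, small_bundle):
        table = clean_cohort(small_bundle.respondents, small_bundle.responses,
                             small_bundle.translation_key, small_bundle.ontology,
                             small_bundle.frd_curies)
        ordinal_cols = [c for c, k in table.kinds.items()
                        if k == "ordinal" and c in table.features.columns]
        assert ordinal_cols
        observed = table.features[ordinal_cols].stack().dropna()
        assert observed.max() > 1          # not binarized
        assert observed.between(0, 5).all()


def _mcar_table(n=400, p=8, missing=0.2, seed=0) -> tuple:
    """Correlated mixed table with ground truth, plus an MCAR-masked copy."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n, 2))
    cols, kinds = {}, {}
    for j in range(p):
        w = rng.normal(size=2)
        signal = latent @ w + rng.normal(scale=0.6, size=n)
        if j % 2:
            cols[f"f{j}"] = (signal > 0).astype(float)
            kinds[f"f{j}"] = "binary"
        else:
            cols[f"f{j}"] = np.clip(np.round(2.5 + signal), 0, 5)
            kinds[f"f{j}"] = "ordinal"
    truth = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
    mask = rng.random(truth.shape) < missing
    masked = truth.mask(mask)
    outcomes = pd.DataFrame({"MONDO:1": rng.integers(0, 2, n)}, index=truth.index)
    table = FeatureTable(features=masked, outcomes=outcomes, kinds=kinds)
    return table, truth, mask


class TestImputeMissforest:
    def test_complete_table_returned_unchanged(self):
        table, truth, _ = _mcar_table(missing=0.0)
        out = impute_missforest(table, seed=0)
        pd.testing.assert_frame_equal(out.features, table.features)

    def test_observed_cells_never_modified(self):
        table, truth, mask = _mcar_table(seed=3)
        out = impute_missforest(table, max_iter=3, n_trees=30, seed=3)
        observed = ~mask
        np.testing.assert_array_equal(
            out.features.to_numpy()[observed], truth.to_numpy()[observed])
        assert not out.features.isna().any().any()

    def test_deterministic_column_is_recovered(self):
        # f_b is an exact copy of f_a; a single masked cell must be restored
        n = 200
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, n).astype(float)
        features = pd.DataFrame({
            "fa": a, "fb": a.copy(),
            "fc": rng.integers(0, 2, n).astype(float)})
        features.loc[features.index[5], "fb"] = np.nan
        table = FeatureTable(features=features,
                             outcomes=pd.DataFrame(index=features.index),
                             kinds={"fa": "binary", "fb": "binary", "fc": "binary"})
        out = impute_missforest(table, max_iter=3, n_trees=30, seed=1)
        assert out.features.loc[features.index[5], "fb"] == a[5]

    def test_all_missing_column_dropped_with_warning(self):
        table, _, _ = _mcar_table(seed=4)
        table.features["dead"] = np.nan
        table.kinds["dead"] = "binary"
        with pytest.warns(UserWarning, match="dead"):
            out = impute_missforest(table, max_iter=2, n_trees=10, seed=4)
        assert "dead" not in out.features.columns

    def test_beats_mean_imputation_on_mcar_data(self):
        """NRMSE of the forest imputer below the mean-imputer baseline."""
        wins = 0
        for seed in range(3):
            table, truth, mask = _mcar_table(n=400, p=8, seed=10 + seed)
            out = impute_missforest(table, max_iter=3, n_trees=50, seed=seed)
            err_rf = ((out.features.to_numpy() - truth.to_numpy())[mask] ** 2).mean()
            means = table.features.mean()
            mean_filled = table.features.fillna(means)
            err_mean = ((mean_filled.to_numpy() - truth.to_numpy())[mask] ** 2).mean()
            if err_rf < err_mean:
                wins += 1
        assert wins >= 2


class TestSelectFeatures:
    def _table_with_informative_feature(self, n=1500, seed=0):
        rng = np.random.default_rng(seed)
        outcome = rng.integers(0, 2, n)
        cols = {"signal": outcome.astype(float)}
        for j in range(9):
            cols[f"noise{j}"] = rng.integers(0, 2, n).astype(float)
        features = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
        outcomes = pd.DataFrame({"MONDO:1": outcome}, index=features.index)
        kinds = {c: "binary" for c in cols}
        return FeatureTable(features=features, outcomes=outcomes, kinds=kinds)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_informative_feature_ranked_first(self, seed):
        table = self._table_with_informative_feature(seed=seed)
        ranked = select_features(table, "MONDO:1", seed=seed)
        assert ranked and ranked[0] == "signal"

    def test_single_class_outcome_rejected(self):
        table = self._table_with_informative_feature()
        table.outcomes["MONDO:1"] = 1
        with pytest.raises(ValueError, match="single class"):
            select_features(table, "MONDO:1", seed=0)

    def test_pure_noise_panel_retains_nothing_or_little(self):
        rng = np.random.default_rng(5)
        n = 800
        features = pd.DataFrame(
            {f"n{j}": rng.integers(0, 2, n).astype(float) for j in range(8)},
            index=[f"P{i}" for i in range(n)])
        outcomes = pd.DataFrame({"MONDO:1": rng.integers(0, 2, n)},
                                index=features.index)
        table = FeatureTable(features=features, outcomes=outcomes,
                             kinds={c: "binary" for c in features.columns})
        try:
            ranked = select_features(table, "MONDO:1", seed=5)
        except ValueError:
            ranked = []
        assert len(ranked) <= 3


class TestFitLogistic:
    def test_single_predictor_matches_2x2_closed_form(self):
        # (a, b, c, d) = (30, 70, 10, 90): OR = ad/bc = 3.857142...
        rows = ([{"x": 1.0, "y": 1}] * 30 + [{"x": 1.0, "y": 0}] * 70
                + [{"x": 0.0, "y": 1}] * 10 + [{"x": 0.0, "y": 0}] * 90)
        frame = pd.DataFrame(rows, index=[f"P{i}" for i in range(200)])
        table = FeatureTable(
            features=frame[["x"]].astype(float),
            outcomes=frame[["y"]].rename(columns={"y": "MONDO:1"}),
            kinds={"x": "binary"})
        result, = fit_logistic(table, "MONDO:1", ["x"])
        assert result.odds_ratio == pytest.approx(30 * 90 / (70 * 10), abs=1e-4)
        assert result.ci_low < result.odds_ratio < result.ci_high

    def test_null_predictor_ci_covers_one(self):
        covered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 3000
            x = rng.integers(0, 2, n).astype(float)
            y = rng.integers(0, 2, n)
            table = FeatureTable(
                features=pd.DataFrame({"x": x}, index=[f"P{i}" for i in range(n)]),
                outcomes=pd.DataFrame({"MONDO:1": y}, index=[f"P{i}" for i in range(n)]),
                kinds={"x": "binary"})
            r, = fit_logistic(table, "MONDO:1", ["x"], adjust=False)
            if r.ci_low <= 1.0 <= r.ci_high:
                covered += 1
        assert covered >= 8

    def test_perfect_separation_flagged_not_dropped(self):
        n = 60
        x = np.r_[np.ones(30), np.zeros(30)]
        y = x.astype(int)                   # outcome identical to predictor
        table = FeatureTable(
            features=pd.DataFrame({"x": x}, index=[f"P{i}" for i in range(n)]),
            outcomes=pd.DataFrame({"MONDO:1": y}, index=[f"P{i}" for i in range(n)]),
            kinds={"x": "binary"})
        r, = fit_logistic(table, "MONDO:1", ["x"])
        assert r.separation_flag
        assert r.ci_high == np.inf

    def test_output_schema_matches_report_columns(self):
        rows = ([{"x": 1.0, "y": 1}] * 25 + [{"x": 1.0, "y": 0}] * 75
                + [{"x": 0.0, "y": 1}] * 12 + [{"x": 0.0, "y": 0}] * 88)
        frame = pd.DataFrame(rows, index=[f"P{i}" for i in range(200)])
        table = FeatureTable(
            features=frame[["x"]].astype(float),
            outcomes=frame[["y"]].rename(columns={"y": "MONDO:1"}),
            kinds={"x": "binary"})
        out = results_frame(fit_logistic(table, "MONDO:1", ["x"]))
        assert list(out.columns) == TABLE_COLUMNS
        assert len(out) == 1


class TestBonferroni:
    def test_identity_single_test(self):
        assert bonferroni_adjust([0.01]) == [0.01]

    def test_definition_two_tests(self):
        assert bonferroni_adjust([0.01, 0.2]) == [0.02, 0.4]

    def test_capping_at_one(self):
        assert bonferroni_adjust([0.9, 0.8], m=5) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_scale_exact_and_monotone(self, pvals):
        adjusted = bonferroni_adjust(pvals)
        m = len(pvals)
        for p, q in zip(pvals, adjusted):
            assert q == min(1.0, m * p)      # machine-precision identity
            assert q >= p
            assert q <= 1.0


class TestVIF:
    def test_orthogonal_features_have_unit_vif(self):
        x = pd.DataFrame({"a": [1, 1, -1, -1, 1, 1, -1, -1.0],
                          "b": [1, -1, 1, -1, 1, -1, 1, -1.0]})
        vifs = compute_vif(x)
        assert vifs["a"] == pytest.approx(1.0, abs=1e-10)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_feature_reported_absent(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        x = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
        vifs = compute_vif(x)
        assert vifs["a"] is None and vifs["b"] is None
        assert vifs["c"] is not None

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 200
        z = rng.normal(size=n)
        x = pd.DataFrame({
            "a": z + rng.normal(scale=0.5, size=n),
            "b": z + rng.normal(scale=0.8, size=n),
            "c": rng.normal(size=n),
        })
        vifs = compute_vif(x)
        for j, col in enumerate(x.columns):
            yj = x[col].to_numpy()
            others = x.drop(columns=[col]).to_numpy()
            design = np.column_stack([np.ones(n), others])
            # explicit normal equations
            beta = np.linalg.solve(design.T @ design, design.T @ yj)
            resid = yj - design @ beta
            r2 = 1 - resid @ resid / ((yj - yj.mean()) @ (yj - yj.mean()))
            assert vifs[col] == pytest.approx(1 / (1 - r2), abs=1e-6)

    def test_single_feature_is_absent(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert compute_vif(x) == {"a": None}
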