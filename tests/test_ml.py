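"""Consensus feature selection, model evaluation, stepwise ORs, robustness."""

import numpy as np
import pandas as pd
import pytest

import cadomics as cd
from cadomics.ml import FeatureTable, _metrics


def _table(n=300, p=20, informative=3, effect=2.0, seed=0, case_frac=0.3):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < case_frac).astype(int)
    y[:2] = [0, 1]  # both classes guaranteed
    X = rng.normal(size=(n, p))
    X[y == 1, :informative] += effect
    idx = pd.Index([f"s{i}" for i in range(n)])
    return FeatureTable(
        pd.DataFrame(X, index=idx, columns=[f"f{i:02d}" for i in range(p)]),
        pd.Series(y, index=idx),
    )


class TestAssembly:
    def test_shapes_and_labels(self, small_cohort):
        co = small_cohort
        norm = cd.normalize_metabolites(co.metabolites)
        hap = cd.call_haplotypes(co.genotypes).haplotype
        ft = cd.assemble_features(co.cohort, norm.values, haplotype=hap)
        # 20 metabolites + age/bmi/sex + 6 meds + hap2/hap3
        assert ft.X.shape == (160, 20 + 3 + 6 + 2)
        assert ft.y.sum() == (co.cohort["group"] == "CAD").sum()

    def test_highrisk_vs_cad_subset(self, small_cohort):
        co = small_cohort
        norm = cd.normalize_metabolites(co.metabolites)
        ft = cd.assemble_features(co.cohort, norm.values, task="highrisk_vs_cad")
        assert len(ft.y) == (co.cohort["group"] != "control").sum()
        assert ft.y.sum() == (co.cohort["group"] == "CAD").sum()


class TestConsensusSelect:
    def test_per_iteration_budget_and_conservation(self):
        """RF and SVM each select exactly the LASSO count k per iteration."""
        t = _table()
        r = cd.consensus_select(t, B=4, seed=1)
        expected = sum(3 * k for k in r.k_per_iteration if k > 0)
        assert r.total_selections == expected
        for method in ("lasso", "rf", "svm"):
            assert r.counts[method].sum() == sum(k for k in r.k_per_iteration if k > 0)

    def test_determinism(self):
        t = _table()
        a = cd.consensus_select(t, B=1, seed=9)
        b = cd.consensus_select(t, B=1, seed=9)
        assert a.counts.equals(b.counts)
        assert a.k_per_iteration == b.k_per_iteration

    def test_planted_features_rank_high(self):
        t = _table(n=400, p=30, informative=4, effect=2.0, seed=2)
        r = cd.consensus_select(t, B=10, seed=3)
        top8 = cd.top_k_features(r, 8)
        assert all(f"f{i:02d}" in top8 for i in range(4))

    def test_too_few_features_rejected(self):
        t = _table(p=2)
        with pytest.raises(ValueError):
            cd.consensus_select(FeatureTable(t.X.iloc[:, :1], t.y), B=1)


class TestTopK:
    def _ranking(self):
        counts = pd.DataFrame(
            {"lasso": [5, 9, 1], "rf": [5, 1, 5], "svm": [5, 5, 9]},
            index=["b_feat", "a_feat", "c_feat"],
        )
        counts["total"] = counts.sum(axis=1)
        ordered = counts.assign(name=counts.index).sort_values(
            ["total", "lasso", "name"], ascending=[False, False, True], kind="stable"
        ).drop(columns="name")
        ordered["rank"] = range(1, 4)
        return cd.FeatureRanking(ordered, [5], 1)

    def test_tie_break_prefers_lasso_then_name(self):
        # all totals equal (15); lasso 9 wins; b_feat before c_feat at lasso tie?
        top = cd.top_k_features(self._ranking(), 3)
        assert top[0] == "a_feat"  # highest lasso count among total ties
        assert top == ["a_feat", "b_feat", "c_feat"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            cd.top_k_features(self._ranking(), 4)


class TestTrainAndEvaluate:
    def test_separable_data_perfect(self):
        t = _table(n=200, p=10, informative=3, effect=8.0, seed=4)
        ev = cd.train_and_evaluate(t, list(t.X.columns), scheme="holdout",
                                   model="rf", seed=0)
        assert ev.metrics["auc"] == pytest.approx(1.0, abs=1e-9)
        assert ev.metrics["brier"] < 0.05

    def test_permuted_labels_auc_near_half(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = _table(n=300, p=10, informative=0, effect=0.0, seed=seed)
            ev = cd.train_and_evaluate(t, list(t.X.columns), scheme="cv10",
                                       model="lasso", seed=seed)
            aucs.append(ev.metrics["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_xgboost_grid_enumerates_75(self):
        assert len(cd.xgb_grid_combinations()) == 75
        combos = {tuple(sorted(c.items())) for c in cd.xgb_grid_combinations()}
        assert len(combos) == 75

    def test_cv10_has_ten_folds(self):
        t = _table(n=250, p=8, seed=5)
        ev = cd.train_and_evaluate(t, list(t.X.columns), scheme="cv10",
                                   model="lasso", seed=1)
        assert len(ev.per_fold) == 10

    def test_empty_feature_list_rejected(self):
        t = _table()
        with pytest.raises(ValueError):
            cd.train_and_evaluate(t, [], model="rf")


class TestAucCrossCheck:
    @pytest.mark.parametrize("seed", range(5))
    def test_rank_statistic_equals_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(400) < 0.35).astype(int)
        y[:2] = [0, 1]
        scores = rng.normal(size=400) + 0.8 * y
        # introduce ties
        scores = np.round(scores, 2)
        assert cd.auc_rank(y, scores) == pytest.approx(
            cd.auc_trapezoid(y, scores), abs=1e-10
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = (rng.random(300) < 0.4).astype(int)
        s = rng.normal(size=300) + y
        assert cd.auc_rank(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestBackwardStepwise:
    def test_single_binary_predictor_matches_contingency_or(self):
        """2×2 table 40/10 vs 20/30 → logistic OR equals (40·30)/(10·20) = 6."""
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)].astype(int)
        idx = pd.Index([f"s{i}" for i in range(100)])
        t = FeatureTable(pd.DataFrame({"exposed": x}, index=idx),
                         pd.Series(y, index=idx))
        out = cd.backward_stepwise_or(t, ["exposed"])
        assert "exposed" in out.index
        assert out.loc["exposed", "odds_ratio"] == pytest.approx(6.0, abs=1e-6)

    def test_pure_noise_mostly_eliminated(self):
        kept = []
        for seed in range(5):
            t = _table(n=600, p=10, informative=0, effect=0.0, seed=seed)
            out = cd.backward_stepwise_or(t, list(t.X.columns))
            kept.append(len(out))
        assert sum(k <= 1 for k in kept) >= 4

    def test_empty_feature_list_gives_empty_table(self):
        t = _table()
        out = cd.backward_stepwise_or(t, [])
        assert out.empty


@pytest.fixture(scope="module")
def imbalanced(small_cohort):
    co = small_cohort
    norm = cd.normalize_metabolites(co.metabolites)
    return cd.assemble_features(co.cohort, norm.values)


class TestBalanceExperiments:
    def test_subsample_balances_training(self, imbalanced):
        feats = list(imbalanced.X.columns[:8]) + ["age", "sex_male"]
        ev, keep = cd.balance_experiments(imbalanced, feats,
                                          mode="subsample_1to1", seed=0)
        y_train = imbalanced.y.loc[keep]
        assert y_train.sum() == (1 - y_train).sum()

    def test_matched_pairs_respect_contract(self, imbalanced):
        feats = list(imbalanced.X.columns[:8]) + ["age", "sex_male"]
        ev, keep = cd.balance_experiments(imbalanced, feats,
                                          mode="match_age_sex", seed=0)
        y = imbalanced.y.loc[keep]
        cases = [s for s in keep if y[s] == 1]
        ctrls = [s for s in keep if y[s] == 0]
        assert len(cases) == len(ctrls)
        # every matched control shares sex with some case within the caliper
        X = imbalanced.X
        for c in ctrls:
            ok = any(
                X.loc[c, "sex_male"] == X.loc[k, "sex_male"]
                and abs(X.loc[c, "age"] - X.loc[k, "age"]) <= 5.0
                for k in cases
            )
            assert ok

    def test_same_seed_identical_sets(self, imbalanced):
        feats = list(imbalanced.X.columns[:8]) + ["age", "sex_male"]
        _, k1 = cd.balance_experiments(imbalanced, feats, mode="match_age_sex", seed=3)
        _, k2 = cd.balance_experiments(imbalanced, feats, mode="match_age_sex", seed=3)
        assert list(k1) == list(k2)

    def test_validation_never_in_training(self, imbalanced):
        from sklearn.model_selection import train_test_split

        feats = list(imbalanced.X.columns[:8]) + ["age", "sex_male"]
        _, keep = cd.balance_experiments(imbalanced, feats,
                                         mode="subsample_1to1", seed=5)
        _, idx_te = train_test_split(imbalanced.X.index, train_size=0.8,
                                     stratify=imbalanced.y, random_state=5)
        assert set(keep).isdisjoint(idx_te)


class TestInteractionFeatures:
    def test_adds_products_and_keeps_originals(self, feature_table):
        wide = cd.interaction_features(feature_table, "statin")
        n_mets = len(feature_table.metabolite_features)
        assert wide.X.shape[1] == feature_table.X.shape[1] + n_mets
        met = feature_table.metabolite_features[0]
        np.testing.assert_allclose(
            wide.X[f"statin_x_{met}"],
            feature_table.X["statin"] * feature_table.X[met],
        )

    def test_absent_flag_rejected(self, feature_table):
        with pytest.raises(ValueError):
            cd.interaction_features(feature_table, "not_a_column")


class TestCalibration:
    def test_calibrated_probabilities(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 10000)
        y = (rng.random(10000) < p).astype(int)
        rep = cd.calibration_report(p, y)
        assert rep.slope == pytest.approx(1.0, abs=0.05)
        assert rep.brier == pytest.approx(np.mean(p * (1 - p)), abs=0.01)

    def test_constant_half_on_balanced_labels(self):
        y = np.r_[np.zeros(500), np.ones(500)].astype(int)
        p = np.full(1000, 0.5)
        rep = cd.calibration_report(p, y)
        assert rep.brier == pytest.approx(0.25, abs=1e-12)

    def test_overconfident_slope_below_one_improves_after_platt(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 8000)
        y = (rng.random(8000) < p).astype(int)
        z = 2 * np.log(p / (1 - p))  # logit doubled → overconfident
        p_over = 1 / (1 + np.exp(-z))
        rep = cd.calibration_report(p_over, y, recalibrate="platt", seed=2)
        assert rep.slope < 1.0
        assert abs(rep.slope_after - 1.0) < abs(rep.slope - 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cd.calibration_report(np.array([0.2, 0.8]), np.array([1, 1]))


def test_metrics_ranges():
    rng = np.random.default_rng(2)
    y = (rng.random(300) < 0.4).astype(int)
    p = np.clip(rng.random(300) * 0.6 + 0.2 * y, 0, 1)
    m = _metrics(y, p)
    for key in ("auc", "accuracy", "sensitivity", "specificity", "auc_pr", "brier"):
        assert 0.0 <= m[key] <= 1.0
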