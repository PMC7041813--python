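"""Elastic-net model machinery: AUC, repeated validation, comparisons."""

import numpy as np
import pandas as pd
import pytest

from petrad.model import (
    ModelRun,
    ModelRunSet,
    auc,
    build_design,
    compare_models,
    external_validate,
    fit_elastic_net_cv,
    frequency_ranking,
    repeated_train_validate,
)


def _logistic_data(rng, n=150, p=6, beta=None, intercept=0.0):
    x = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)])
    eta = np.full(n, intercept)
    if beta:
        for name, b in beta.items():
            eta = eta + b * x[name].to_numpy()
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return x, y, eta


class TestAUC:
    def test_perfect_ordering(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_anti_ordering(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_hand_computed_three_quarters(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])


class TestElasticNetFit:
    def test_planted_separator_dominates(self, rng):
        x, y, _ = _logistic_data(rng, n=200, beta={"f0": 3.0})
        model = fit_elastic_net_cv(x, y, folds=5, n_lambda=10, random_state=0)
        assert "f0" in model.selected_features
        assert abs(model.coef["f0"]) == max(abs(model.coef))

    def test_duplicated_columns_share_weight(self, rng):
        """Grouping property: elastic net splits weight across duplicates."""
        x, y, _ = _logistic_data(rng, n=300, beta={"f0": 2.0})
        x["f0_copy"] = x["f0"]
        model = fit_elastic_net_cv(x, y, folds=5, n_lambda=10, random_state=0)
        assert model.coef["f0"] == pytest.approx(model.coef["f0_copy"], rel=0.15)

    def test_single_class_rejected(self, rng):
        x, _, _ = _logistic_data(rng, n=30)
        with pytest.raises(ValueError, match="single class"):
            fit_elastic_net_cv(x, np.ones(30, dtype=int), folds=5)

    def test_nonfinite_design_rejected(self, rng):
        x, y, _ = _logistic_data(rng, n=30)
        x.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing or non-finite"):
            fit_elastic_net_cv(x, y, folds=5)


class TestRepeatedTrainValidate:
    def test_null_endpoint_auc_near_half(self, rng):
        x, _, _ = _logistic_data(rng, n=252, p=5)
        y = (rng.random(252) < 0.4).astype(int)
        runs = repeated_train_validate(x, y, n_rep=20, folds=5, n_lambda=8, seed=3)
        se = runs.aucs.std(ddof=1) / np.sqrt(len(runs.aucs))
        assert abs(runs.aucs.mean() - 0.5) < max(3 * se, 0.05)

    def test_planted_signal_recovered(self, rng):
        x, y, eta = _logistic_data(rng, n=252, beta={"f0": 1.2, "f1": -0.8})
        oracle = auc(eta, y)
        runs = repeated_train_validate(x, y, n_rep=15, folds=5, n_lambda=10, seed=4)
        assert runs.aucs.mean() == pytest.approx(oracle, abs=0.06)

    def test_same_seed_reproduces_everything(self, rng):
        x, y, _ = _logistic_data(rng, n=120, beta={"f0": 1.0})
        r1 = repeated_train_validate(x, y, n_rep=3, folds=5, n_lambda=8, seed=9)
        r2 = repeated_train_validate(x, y, n_rep=3, folds=5, n_lambda=8, seed=9)
        assert np.array_equal(r1.aucs, r2.aucs)
        for a, b in zip(r1.runs, r2.runs):
            pd.testing.assert_series_equal(a.model.coef, b.model.coef)
            assert np.array_equal(a.val_idx, b.val_idx)

    def test_train_validation_disjoint(self, rng):
        x, y, _ = _logistic_data(rng, n=100)
        runs = repeated_train_validate(x, y, n_rep=2, folds=5, n_lambda=5, seed=0)
        for run in runs.runs:
            assert not set(run.train_idx) & set(run.val_idx)
            assert len(run.train_idx) + len(run.val_idx) == 100


class TestFrequencyRanking:
    @staticmethod
    def _runset(selections, columns):
        runs = []
        for sel in selections:
            coef = pd.Series(0.0, index=columns)
            coef[sel] = 1.0
            model = type("M", (), {"coef": coef, "selected_features": list(sel)})()
            runs.append(ModelRun(train_idx=None, val_idx=None, model=model, val_auc=0.6))
        return ModelRunSet(runs=runs)

    def test_counts_and_ordering(self):
        runs = self._runset(
            [["a", "b"], ["a"], ["a", "c"]], columns=["a", "b", "c", "d"]
        )
        ranking = frequency_ranking(runs)
        assert ranking.iloc[0].tolist() == ["a", 3]
        assert dict(zip(ranking["feature"], ranking["count"])) == {
            "a": 3, "b": 1, "c": 1, "d": 0,
        }
        # lexicographic tie-break between b and c
        assert ranking["feature"].tolist()[1:3] == ["b", "c"]

    def test_always_selected_counts_n_rep(self, rng):
        x, y, _ = _logistic_data(rng, n=200, beta={"f0": 3.0})
        runs = repeated_train_validate(x, y, n_rep=5, folds=5, n_lambda=8, seed=1)
        ranking = frequency_ranking(runs).set_index("feature")
        assert ranking.loc["f0", "count"] == 5


class TestCompareModels:
    @staticmethod
    def _runset_from_aucs(aucs):
        runs = [
            ModelRun(train_idx=None, val_idx=None, model=None, val_auc=float(a))
            for a in aucs
        ]
        return ModelRunSet(runs=runs)

    def test_identical_samples_not_significant(self):
        a = self._runset_from_aucs([0.6] * 10)
        p, sig = compare_models(a, self._runset_from_aucs([0.6] * 10))
        assert p == 1.0 and not sig

    def test_detects_auc_shift(self, rng):
        a = self._runset_from_aucs(rng.normal(0.60, 0.03, 100))
        b = self._runset_from_aucs(rng.normal(0.70, 0.03, 100))
        p, sig = compare_models(a, b)
        assert sig and p < 1e-6

    def test_symmetric_in_arguments(self, rng):
        a = self._runset_from_aucs(rng.normal(0.6, 0.05, 30))
        b = self._runset_from_aucs(rng.normal(0.65, 0.05, 30))
        assert compare_models(a, b)[0] == pytest.approx(compare_models(b, a)[0])


class TestDesignAndExternal:
    @staticmethod
    def _clinical(rng, n=40):
        return pd.DataFrame(
            {
                "Age": rng.normal(65, 8, n),
                "Gender": rng.choice(["male", "female"], n),
                "Histology": rng.choice(["adeno", "squamous", "nos_other"], n),
                "T_status": rng.choice([1, 2, 3, 4], n),
                "N_status": rng.choice([0, 1, 2, 3], n),
                "Stage": rng.choice(["IIIA", "IIIB"], n),
                "GTV": rng.lognormal(4, 0.5, n),
            }
        )

    def test_clin_family_columns(self, rng):
        design = build_design(None, self._clinical(rng), family="clin")
        assert {"Age", "GTV", "Gender", "T_status", "N_status"} <= set(design.columns)
        assert any(c.startswith("Histology_") for c in design.columns)
        assert any(c.startswith("Stage_") for c in design.columns)

    def test_all_family_is_union(self, rng):
        clinical = self._clinical(rng)
        feats = pd.DataFrame({"shape_Sphericity__MTV25": rng.random(40)})
        clin_only = build_design(None, clinical, family="clin")
        both = build_design(feats, clinical, family="all")
        assert set(clin_only.columns) < set(both.columns)
        assert "shape_Sphericity__MTV25" in both.columns

    def test_empty_radiomics_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="selection is empty"):
            build_design(pd.DataFrame(index=range(40)), self._clinical(rng), family="rad")

    def test_missing_values_rejected(self, rng):
        clinical = self._clinical(rng)
        clinical.loc[0, "Age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(None, clinical, family="clin")

    def test_zero_slope_model_gives_half_auc(self, rng):
        x, y, _ = _logistic_data(rng, n=60)
        from petrad.model import FittedModel

        model = FittedModel(
            coef=pd.Series(0.0, index=x.columns), intercept=0.3, c_selected=1.0,
            l1_ratio=0.5, mean=x.mean(), std=x.std(ddof=0),
        )
        assert external_validate(model, x, y) == pytest.approx(0.5)

    def test_shuffled_external_labels_near_half(self, rng):
        x, y, _ = _logistic_data(rng, n=400, beta={"f0": 2.0})
        model = fit_elastic_net_cv(x, y, folds=5, n_lambda=8, random_state=0)
        y_shuffled = rng.permutation(y)
        assert external_validate(model, x, y_shuffled) == pytest.approx(0.5, abs=0.1)

    def test_external_same_distribution_close_to_internal(self, rng):
        x, y, _ = _logistic_data(rng, n=300, beta={"f0": 1.5})
        runs = repeated_train_validate(x, y, n_rep=8, folds=5, n_lambda=8, seed=2)
        x_ext, y_ext, _ = _logistic_data(rng, n=300, beta={"f0": 1.5})
        ext_auc = external_validate(runs.best_run.model, x_ext, y_ext)
        assert ext_auc == pytest.approx(runs.aucs.mean(), abs=0.12)

    def test_schema_mismatch_lists_missing(self, rng):
        x, y, _ = _logistic_data(rng, n=60, beta={"f0": 1.0})
        model = fit_elastic_net_cv(x, y, folds=5, n_lambda=5, random_state=0)
        with pytest.raises(ValueError, match="missing columns"):
            external_validate(model, x.drop(columns="f0"), y)
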