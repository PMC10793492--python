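import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from oracles import cindex_bruteforce
from tilarch.errors import ValidationError
from tilarch.survival import (
    RiskModel,
    adjusted_cox,
    concordance,
    cox_partial_loglik,
    evaluate,
    fit_model,
    split_cohort,
    tune_threshold,
    two_group_cox,
)
from tilarch.synthetic import simulate_survival_times


def _surv(n, rng, risk=None, cens=0.01, h0=0.02):
    risk = np.zeros(n) if risk is None else risk
    t, e = simulate_survival_times(risk, h0, cens, rng)
    return pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                         "time": t, "event": e})


class TestSplitCohort:
    def test_nine_patients_split_six_three(self, rng):
        surv = _surv(9, rng)
        sp = split_cohort(surv, seed=0)
        assert len(sp.train_ids) == 6 and len(sp.test_ids) == 3
        assert set(sp.train_ids) | set(sp.test_ids) == set(surv["patient_id"])
        assert not set(sp.train_ids) & set(sp.test_ids)

    def test_same_seed_identical_split(self, rng):
        surv = _surv(40, rng)
        assert split_cohort(surv, seed=5).train_ids == \
            split_cohort(surv, seed=5).train_ids

    def test_stratified_split_preserves_event_fraction(self, rng):
        surv = _surv(100, rng)
        surv["event"] = ([1] * 30 + [0] * 70)
        sp = split_cohort(surv, seed=1, stratify_by="event")
        test_events = surv.set_index("patient_id").loc[sp.test_ids, "event"].sum()
        expected = 0.3 * len(sp.test_ids)
        assert abs(test_events - expected) <= 1

    def test_too_small_cohort_rejected(self, rng):
        with pytest.raises(ValidationError):
            split_cohort(_surv(2, rng))


class TestTwoGroupCox:
    def test_matches_lifelines_efron_with_ties(self, rng):
        for _ in range(3):
            n = 100
            x = rng.integers(0, 2, n)
            t = np.ceil(rng.exponential(20 * np.exp(-0.7 * x)))
            e = (rng.uniform(size=n) < 0.75).astype(int)
            mine = two_group_cox(t, e, x)
            ref = CoxPHFitter().fit(
                pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e").summary.loc["x"]
            assert mine["beta"] == pytest.approx(ref["coef"], abs=1e-5)
            assert mine["se"] == pytest.approx(ref["se(coef)"], abs=1e-5)

    def test_partial_loglik_matches_lifelines_no_ties(self, rng):
        t = rng.exponential(10, size=60)
        e = np.ones(60, int)
        x = rng.normal(size=60)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        ll = cox_partial_loglik(cph.params_["x"] * x, t, e)
        assert ll == pytest.approx(cph.log_likelihood_, rel=1e-9)


class TestFitModel:
    def _planted(self, rng, n=150, p=300, k=3, beta=1.2, names=None):
        cols = names or [f"f{j}" for j in range(p)]
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=cols,
                         index=[f"P{i}" for i in range(n)])
        planted = cols[:k]
        risk = X[planted].to_numpy().sum(axis=1) * beta / np.sqrt(k)
        t, e = simulate_survival_times(risk, 0.02, 0.005, rng)
        surv = pd.DataFrame({"patient_id": X.index, "time": t, "event": e})
        return X, surv, planted

    def test_infinite_penalty_yields_flagged_null_model(self, rng):
        X, surv, _ = self._planted(rng)
        with pytest.warns(UserWarning, match="null model"):
            m = fit_model(X, surv, folds=5, seed=0, alphas=[1e6], tune=False)
        assert m.is_null and m.support == []

    def test_risk_score_is_linear_predictor(self, rng):
        X, surv, _ = self._planted(rng)
        m = fit_model(X, surv, folds=5, seed=0, tune=False)
        z = (X[m.feature_names].to_numpy() - m.mean) / m.sd
        np.testing.assert_allclose(m.risk_score(X).to_numpy(), z @ m.coef)

    def test_planted_support_recovered(self, rng):
        X, surv, planted = self._planted(rng, n=200, p=400, k=3)
        m = fit_model(X, surv, folds=10, seed=1, tune=False)
        assert sum(f in m.support for f in planted) >= 2
        for f in planted:
            if f in m.support:
                assert m.coef[m.feature_names.index(f)] > 0  # no sign flips

    def test_standardizer_fit_on_training_only(self, rng):
        X, surv, _ = self._planted(rng)
        m = fit_model(X, surv, folds=5, seed=0, tune=False)
        np.testing.assert_allclose(m.mean, X[m.feature_names].mean(0), atol=1e-9)
        # scoring shifted test data reuses the training means: scores shift too
        shifted = X + 10.0
        np.testing.assert_allclose(
            m.risk_score(shifted).to_numpy(),
            (m.standardize(X) + 10.0 / m.sd) @ m.coef, rtol=1e-9)

    def test_constant_features_dropped_with_warning(self, rng):
        X, surv, _ = self._planted(rng)
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_model(X, surv, folds=5, seed=0, tune=False)
        assert "const" not in m.feature_names

    def test_no_events_rejected(self, rng):
        X, surv, _ = self._planted(rng)
        surv["event"] = 0
        with pytest.raises(ValidationError):
            fit_model(X, surv, folds=5, seed=0)

    def test_json_roundtrip(self, rng, tmp_path):
        X, surv, _ = self._planted(rng)
        m = fit_model(X, surv, folds=5, seed=0, tune=True)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = RiskModel.from_json(path)
        np.testing.assert_allclose(m.coef, m2.coef)
        assert m.threshold == m2.threshold
        np.testing.assert_allclose(m.risk_score(X), m2.risk_score(X))


class TestTuneThreshold:
    def test_separable_scores_cut_between_halves(self, rng):
        n = 60
        scores = pd.Series(np.r_[np.zeros(30), np.ones(30)],
                           index=[f"P{i}" for i in range(n)])
        # all early events in the top half
        t = np.r_[rng.uniform(50, 100, 30), rng.uniform(1, 5, 30)]
        surv = pd.DataFrame({"patient_id": scores.index, "time": t,
                             "event": np.ones(n, int)})
        th = tune_threshold(scores, surv)
        assert 0.0 <= th < 1.0

    def test_sign_symmetry_swaps_strata(self, rng):
        n = 80
        scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        t, e = simulate_survival_times(1.5 * scores.to_numpy(), 0.02, 0.01, rng)
        surv = pd.DataFrame({"patient_id": scores.index, "time": t, "event": e})
        th = tune_threshold(scores, surv)
        th_neg = tune_threshold(-scores, surv)
        high = scores > th
        low_neg = -scores <= th_neg
        # the high stratum under s maps into the low stratum under -s
        assert (high == low_neg).mean() > 0.9

    def test_constant_scores_rejected(self, rng):
        scores = pd.Series(np.ones(20), index=[f"P{i}" for i in range(20)])
        with pytest.raises(ValidationError):
            tune_threshold(scores, _surv(20, rng))

    def test_null_scores_hr_ci_covers_one(self, rng):
        # pure-noise scores: the tuned threshold's HR on fresh data is null
        covered = 0
        sims = 25
        for s in range(sims):
            r = np.random.default_rng(1000 + s)
            n = 120
            scores = pd.Series(r.normal(size=n), index=[f"P{i}" for i in range(n)])
            surv = _surv(n, r, cens=0.005)
            th = tune_threshold(scores, surv)
            fresh = pd.Series(r.normal(size=n), index=scores.index)
            t2, e2 = simulate_survival_times(np.zeros(n), 0.02, 0.005, r)
            res = two_group_cox(t2, e2, (fresh > th).to_numpy())
            covered += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert covered >= 0.9 * sims


class TestEvaluate:
    def _model(self, names):
        p = len(names)
        return RiskModel(label="M", feature_names=list(names),
                         impute_median=np.zeros(p), mean=np.zeros(p),
                         sd=np.ones(p), coef=np.r_[1.0, np.zeros(p - 1)],
                         alpha=0.1, threshold=0.0)

    def test_perfectly_antiranked_scores_give_cindex_one(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.ones(5, int)
        score = -t  # earlier event = higher score
        assert concordance(t, e, score) == 1.0

    def test_identical_groups_logrank_p_one(self):
        from lifelines.statistics import logrank_test
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 1])
        res = logrank_test(t, t, e, e)
        assert res.p_value == pytest.approx(1.0)

    def test_cindex_matches_exhaustive_pairs_with_censoring(self, rng):
        n = 20
        t = rng.exponential(10, n)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        s = rng.normal(size=n)
        assert concordance(t, e, s) == pytest.approx(
            cindex_bruteforce(t, e, s), abs=1e-12)

    def test_evaluate_report_fields(self, rng):
        n = 90
        names = ["a", "b"]
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=names,
                         index=[f"P{i}" for i in range(n)])
        model = self._model(names)
        risk = model.risk_score(X).to_numpy()
        t, e = simulate_survival_times(1.2 * risk, 0.02, 0.01, rng)
        surv = pd.DataFrame({"patient_id": X.index, "time": t, "event": e})
        rep = evaluate(model, X, surv)
        assert 0 <= rep.cindex <= 1
        assert rep.hr_ci[0] <= rep.hr <= rep.hr_ci[1]
        assert set(rep.km_curves["group"]) == {"high", "low"}
        assert not rep.degenerate

    def test_degenerate_stratum_flagged(self, rng):
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                         index=[f"P{i}" for i in range(n)])
        model = self._model(["a", "b"])
        model.threshold = 1e9  # nobody is high risk
        surv = _surv(n, rng)
        rep = evaluate(model, X, surv)
        assert rep.degenerate and rep.hr is None


class TestAdjustedCox:
    def _frame(self, rng, n=300, confounded=False):
        risk = rng.normal(size=n)
        age = rng.normal(0, 1, size=n)
        lp = 1.0 * (risk > 0) + (0.8 * age if confounded else 0.0)
        t, e = simulate_survival_times(lp, 0.02, 0.005, rng)
        surv = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                             "time": t, "event": e, "age": age,
                             "stage": rng.choice(["I", "II"], n)})
        groups = pd.Series(np.where(risk > 0, "high", "low"),
                           index=surv["patient_id"])
        return surv, groups

    def test_independent_covariates_leave_hr_stable(self, rng):
        surv, groups = self._frame(rng)
        tab = adjusted_cox(groups, surv, ["age", "stage"])
        uni = tab[(tab["term"] == "risk_high") & (tab["model"] == "univariate")]
        multi = tab[(tab["term"] == "risk_high") & (tab["model"] == "multivariable")]
        assert abs(multi["hr"].iloc[0] - uni["hr"].iloc[0]) / uni["hr"].iloc[0] < 0.10

    def test_collinear_covariate_warns_and_drops(self, rng):
        surv, groups = self._frame(rng, n=100)
        surv["dup"] = (groups.to_numpy() == "high").astype(float)
        with pytest.warns(UserWarning, match="collinear"):
            tab = adjusted_cox(groups, surv, ["dup"])
        assert "dup" not in set(tab["term"])

    def test_null_risk_ci_covers_one_under_strong_covariate(self):
        covered = 0
        sims = 20
        for s in range(sims):
            r = np.random.default_rng(2000 + s)
            n = 150
            age = r.normal(size=n)
            t, e = simulate_survival_times(1.0 * age, 0.02, 0.005, r)
            surv = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                                 "time": t, "event": e, "age": age})
            groups = pd.Series(r.choice(["high", "low"], n),
                               index=surv["patient_id"])
            tab = adjusted_cox(groups, surv, ["age"])
            row = tab[(tab["term"] == "risk_high") &
                      (tab["model"] == "multivariable")].iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 0.9 * sims
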