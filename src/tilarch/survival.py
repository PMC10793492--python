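"""Population-specific LASSO-Cox prognostic models and their evaluation.

The modeling recipe: z-score standardization fit on the training split
only, an L1-penalized Cox proportional-hazards path whose penalty is
chosen by minimizing the mean cross-validated partial-likelihood deviance
(10 folds), a sparse linear risk score from the surviving coefficients,
and a dichotomization threshold tuned on the training data to maximize the
hazard ratio between the two risk strata.  Evaluation reports Kaplan-Meier
curves, the two-sided log-rank test, the hazard ratio with its Wald 95%
confidence interval, and Harrell's concordance index of the continuous
score.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .errors import ValidationError

REQUIRED_SURV_COLUMNS = ("patient_id", "time", "event")


def _check_surv(surv: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_SURV_COLUMNS) - set(surv.columns)
    if missing:
        raise ValidationError(f"survival table lacks columns {sorted(missing)}")
    if not (surv["time"] > 0).all():
        raise ValidationError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValidationError("event flags must be 0/1")
    return surv


# ---------------------------------------------------------------------------
# cohort splitting


@dataclass
class CohortSplit:
    """Train/internal-test patient id partition with population subsets."""

    train_ids: list[str]
    test_ids: list[str]
    populations: dict[str, str] = field(default_factory=dict)

    def subset(self, which: str, population: str | None = None) -> list[str]:
        ids = self.train_ids if which == "train" else self.test_ids
        if population is None:
            return list(ids)
        return [i for i in ids if self.populations.get(i) == population]


def split_cohort(surv: pd.DataFrame, seed: int = 17,
                 stratify_by: str | None = None,
                 train_num: int = 2, total_den: int = 3) -> CohortSplit:
    """Random 2:1 train/test split of a survival table.

    The training set takes ceil(2n/3) patients; an optional stratification
    column keeps each stratum's train fraction as close to 2/3 as the
    integer counts allow.
    """
    surv = _check_surv(surv)
    n = len(surv)
    if n < 3:
        raise ValidationError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    ids = surv["patient_id"].astype(str).to_numpy()
    n_train = math.ceil(train_num * n / total_den)
    if stratify_by is None:
        perm = rng.permutation(n)
        train = set(ids[perm[:n_train]])
    else:
        strata = surv[stratify_by].to_numpy()
        train = set()
        order = []
        for s in pd.unique(strata):
            members = np.flatnonzero(strata == s)
            members = members[rng.permutation(len(members))]
            k = round(len(members) * train_num / total_den)
            train.update(ids[members[:k]])
            order.append((s, members, k))
        # fix rounding drift toward the exact global training size
        while len(train) < n_train:
            for s, members, k in order:
                extra = [ids[m] for m in members if ids[m] not in train]
                if extra:
                    train.add(extra[0])
                    break
            else:
                break
        while len(train) > n_train:
            for s, members, k in order:
                inside = [ids[m] for m in members if ids[m] in train]
                if len(inside) > 1:
                    train.discard(inside[-1])
                    break
            else:
                break
    train_ids = [i for i in ids if i in train]
    test_ids = [i for i in ids if i not in train]
    pops = {}
    if "population" in surv.columns:
        pops = dict(zip(ids, surv["population"].astype(str)))
    return CohortSplit(train_ids, test_ids, pops)


# ---------------------------------------------------------------------------
# partial likelihood utilities


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    lp = np.asarray(lp, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # running logsumexp over the risk set (descending time)
    shift = lp.max()
    logcum = np.log(np.cumsum(np.exp(lp - shift))) + shift
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        if d_idx:
            denom = logcum[j - 1]
            ll += sum(lp[k] for k in d_idx) - len(d_idx) * denom
        i = j
    return float(ll)


def two_group_cox(time: np.ndarray, event: np.ndarray,
                  indicator: np.ndarray, max_iter: int = 50,
                  beta_cap: float = 15.0) -> dict:
    """Cox model with a single binary covariate, Efron tie handling.

    Scalar Newton iteration; returns ``beta``, ``se``, ``hr``, the Wald
    95% CI and two-sided p-value.  Used inside threshold tuning and
    two-strata evaluation where per-cut model fits must be cheap.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(indicator, int)
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    n = len(time)
    # risk-set composition at each distinct event time
    uniq = np.unique(time[event == 1])
    stats = []
    for t in uniq:
        at_risk = time >= t
        r1 = int(x[at_risk].sum())
        r0 = int(at_risk.sum()) - r1
        tied = (time == t) & (event == 1)
        d1 = int(x[tied].sum())
        d = int(tied.sum())
        stats.append((r0, r1, d - d1, d1))
    if not stats:
        raise ValidationError("no events: Cox model undefined")

    def derivs(beta):
        eb = math.exp(beta)
        ll = g = h = 0.0
        for r0, r1, d0, d1 in stats:
            d = d0 + d1
            S = r0 + r1 * eb
            S1 = r1 * eb  # dS/dbeta (= d2S/dbeta2)
            Sd = d0 + d1 * eb
            Sd1 = d1 * eb
            ll += d1 * beta
            for j in range(d):
                A = S - (j / d) * Sd
                A1 = S1 - (j / d) * Sd1
                ll -= math.log(A)
                g_term = A1 / A
                g -= g_term
                h -= (A1 / A) - g_term ** 2  # A2 == A1 for exp terms
            g += d1
        return ll, g, h

    beta = 0.0
    for _ in range(max_iter):
        ll, g, h = derivs(beta)
        if h >= 0:
            break
        step = -g / h
        step = max(min(step, 2.0), -2.0)
        beta += step
        beta = max(min(beta, beta_cap), -beta_cap)
        if abs(step) < 1e-10:
            break
    ll, g, h = derivs(beta)
    se = math.inf if h >= 0 else 1.0 / math.sqrt(-h)
    from scipy.stats import norm
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = 2 * norm.sf(abs(z))

    def _exp(v):  # overflow-safe
        return math.exp(min(v, 700.0)) if math.isfinite(v) else math.inf

    return {
        "beta": beta, "se": se, "hr": math.exp(beta),
        "ci_low": _exp(beta - 1.959963984540054 * se) if math.isfinite(se) else 0.0,
        "ci_high": _exp(beta + 1.959963984540054 * se),
        "p": p,
    }


# ---------------------------------------------------------------------------
# the risk model


@dataclass
class RiskModel:
    """Standardizer + sparse Cox weights + tuned risk threshold.

    ``coef`` is indexed by the training feature columns and is mostly
    zero; ``support`` is the nonzero set.  Means/sds (and imputation
    medians) come from the training data only, so applying the model to a
    test cohort never leaks test statistics.
    """

    label: str
    feature_names: list[str]
    impute_median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    alpha: float
    threshold: float | None = None
    is_null: bool = False

    @property
    def support(self) -> list[str]:
        return [n for n, c in zip(self.feature_names, self.coef) if c != 0]

    def standardize(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValidationError(
                f"feature matrix lacks {len(missing)} model columns")
        mat = X[self.feature_names].to_numpy(float)
        mat = np.where(np.isfinite(mat), mat, self.impute_median)
        return (mat - self.mean) / self.sd

    def risk_score(self, X: pd.DataFrame) -> pd.Series:
        scores = self.standardize(X) @ self.coef
        return pd.Series(scores, index=X.index, name=f"risk_{self.label}")

    def risk_groups(self, X: pd.DataFrame) -> pd.Series:
        if self.threshold is None:
            raise ValidationError("threshold has not been tuned")
        groups = np.where(self.risk_score(X) > self.threshold, "high", "low")
        return pd.Series(groups, index=X.index, name="risk_group")

    def to_json(self, path):
        payload = {
            "label": self.label,
            "feature_names": self.feature_names,
            "impute_median": self.impute_median.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "coef": self.coef.tolist(),
            "alpha": self.alpha,
            "threshold": self.threshold,
            "is_null": self.is_null,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(label=d["label"], feature_names=d["feature_names"],
                   impute_median=np.array(d["impute_median"]),
                   mean=np.array(d["mean"]), sd=np.array(d["sd"]),
                   coef=np.array(d["coef"]), alpha=d["alpha"],
                   threshold=d["threshold"], is_null=d["is_null"])


def fit_model(X: pd.DataFrame, surv: pd.DataFrame, folds: int = 10,
              seed: int = 17, label: str = "M", n_alphas: int = 30,
              alpha_min_ratio: float = 0.01,
              alphas: list[float] | None = None,
              tune: bool = True) -> RiskModel:
    """Fit a LASSO-Cox risk model with CV-deviance penalty selection.

    Rows of ``X`` are matched to ``surv`` by ``patient_id``.  Constant
    features are dropped with a warning; missing values are imputed by the
    training-cohort median before z-scoring.  When ``alphas`` is given the
    grid is used as-is (a single huge value yields the flagged null
    model).  ``tune=True`` also tunes the stratification threshold on the
    training data.
    """
    surv = _check_surv(surv).copy()
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv = surv.set_index("patient_id")
    ids = [str(i) for i in X.index]
    if set(ids) - set(surv.index.astype(str)):
        raise ValidationError("X contains patients absent from the survival table")
    surv = surv.loc[[i for i in ids]]
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if event.sum() == 0:
        raise ValidationError("cannot fit a Cox model with no events")
    if event.sum() < folds:
        raise ValidationError(
            f"need at least {folds} events for {folds}-fold CV")

    mat = X.to_numpy(float)
    med = np.nanmedian(mat, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    mat = np.where(np.isfinite(mat), mat, med)
    sd = mat.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant features")
    names = [c for c, k in zip(X.columns, keep) if k]
    mat = mat[:, keep]
    med = med[keep]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    Z = (mat - mean) / sd

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    common = dict(l1_ratio=1.0, max_iter=100000, tol=1e-6, fit_baseline_model=False)
    if alphas is None:
        path = CoxnetSurvivalAnalysis(
            n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, **common)
        path.fit(Z, y)
        grid = list(path.alphas_)
    else:
        grid = list(alphas)

    if len(grid) > 1:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        dev = np.zeros((folds, len(grid)))
        for k, (tr, te) in enumerate(kf.split(Z)):
            m = CoxnetSurvivalAnalysis(alphas=grid, **common)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Z[tr], y[tr])
            coefs = m.coef_  # (p, n_alphas) over fitted alphas
            fitted = list(m.alphas_)
            lp = Z[te] @ coefs
            for j, a in enumerate(grid):
                jj = fitted.index(a) if a in fitted else None
                if jj is None:
                    dev[k, j] = np.inf
                else:
                    dev[k, j] = -2.0 * cox_partial_loglik(
                        lp[:, jj], time[te], event[te])
        mean_dev = dev.mean(axis=0)
        best = int(np.argmin(mean_dev))
    else:
        best = 0
    alpha = grid[best]

    final = CoxnetSurvivalAnalysis(alphas=[alpha], **common)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Z, y)
    coef = final.coef_[:, 0]
    is_null = not np.any(coef != 0)
    if is_null:
        warnings.warn(f"model {label}: all coefficients shrunk to zero "
                      "(null model)")
    model = RiskModel(label=label, feature_names=names, impute_median=med,
                      mean=mean, sd=sd, coef=coef, alpha=float(alpha),
                      is_null=is_null)
    if tune and not is_null:
        scores = Z @ coef
        surv_fit = surv.reset_index()
        model.threshold = tune_threshold(pd.Series(scores, index=ids), surv_fit)
    return model


def tune_threshold(scores: pd.Series, surv: pd.DataFrame,
                   q_low: float = 0.10, q_high: float = 0.90,
                   n_grid: int = 81, min_frac: float = 0.10,
                   min_events: int = 2) -> float:
    """Training-set risk threshold maximizing the two-strata hazard ratio.

    Candidate cuts are score quantiles between ``q_low`` and ``q_high``;
    a cut is admissible only when both strata contain at least
    ``min_frac`` of the patients and ``min_events`` events.  Ties in HR
    are broken toward the median cut.
    """
    surv = _check_surv(surv).copy()
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv = surv.set_index("patient_id")
    ids = [str(i) for i in scores.index]
    time = surv.loc[ids, "time"].to_numpy(float)
    event = surv.loc[ids, "event"].to_numpy(int)
    s = scores.to_numpy(float)
    if len(np.unique(s)) < 2:
        raise ValidationError("need at least two distinct scores")
    qs = np.linspace(q_low, q_high, n_grid)
    cuts = np.unique(np.quantile(s, qs))
    n = len(s)
    best: tuple[float, float] | None = None  # (hr, -|q-0.5| proxy)
    best_cut = None
    for cut in cuts:
        high = s > cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < max(1, math.ceil(min_frac * n)):
            continue
        if event[high].sum() < min_events or event[~high].sum() < min_events:
            continue
        try:
            hr = two_group_cox(time, event, high)["hr"]
        except ValidationError:
            continue
        # |log HR| separation: symmetric under score-sign reversal, and
        # identical to plain HR maximization for positively oriented scores
        sep = abs(math.log(hr)) if hr > 0 else 0.0
        frac_high = n_high / n
        tiekey = -abs(0.5 - frac_high)
        if best is None or sep > best[0] + 1e-12 or \
                (abs(sep - best[0]) <= 1e-12 and tiekey > best[1]):
            best = (sep, tiekey)
            best_cut = float(cut)
    if best_cut is None:
        raise ValidationError("no admissible threshold cut found")
    return best_cut


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """Risk-stratified evaluation of a model on one cohort."""

    label: str
    cindex: float
    logrank_p: float | None
    hr: float | None
    hr_ci: tuple[float, float] | None
    km_curves: pd.DataFrame | None
    groups: pd.Series
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"label": self.label, "cindex": self.cindex,
                "logrank_p": self.logrank_p, "hr": self.hr,
                "hr_ci": list(self.hr_ci) if self.hr_ci else None,
                "degenerate": self.degenerate}


def concordance(time, event, score) -> float:
    """Harrell's C-index of a risk score (higher score = higher risk)."""
    return float(concordance_index_censored(
        np.asarray(event, int).astype(bool), np.asarray(time, float),
        np.asarray(score, float))[0])


def evaluate(model: RiskModel, X: pd.DataFrame,
             surv: pd.DataFrame) -> EvaluationReport:
    """KM curves, log-rank test, HR (Wald 95% CI) and C-index on a cohort."""
    surv = _check_surv(surv).copy()
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv = surv.set_index("patient_id")
    ids = [str(i) for i in X.index]
    time = surv.loc[ids, "time"].to_numpy(float)
    event = surv.loc[ids, "event"].to_numpy(int)
    scores = model.risk_score(X)
    cidx = concordance(time, event, scores.to_numpy())
    groups = model.risk_groups(X)
    high = (groups == "high").to_numpy()
    if high.all() or (~high).all():
        return EvaluationReport(model.label, cidx, None, None, None, None,
                                groups, degenerate=True)
    res = two_group_cox(time, event, high)
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    curves = []
    for name, sel in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=name)
        tab = km.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        tab["group"] = name
        curves.append(tab)
    return EvaluationReport(
        label=model.label, cindex=cidx, logrank_p=float(lr.p_value),
        hr=res["hr"], hr_ci=(res["ci_low"], res["ci_high"]),
        km_curves=pd.concat(curves, ignore_index=True), groups=groups)


def adjusted_cox(risk_groups: pd.Series, surv: pd.DataFrame,
                 covariates: list[str]) -> pd.DataFrame:
    """Univariate and multivariable Cox tables for risk group + covariates.

    Categorical covariates are dummy-coded; constant or collinear columns
    are dropped with a warning; patients with missing covariates are
    removed listwise (count logged via warning).  Ties: Efron (lifelines
    default).
    """
    surv = _check_surv(surv).copy()
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv = surv.set_index("patient_id")
    ids = [str(i) for i in risk_groups.index]
    df = surv.loc[ids, ["time", "event"] + covariates].copy()
    df["risk_high"] = (risk_groups == "high").astype(int).to_numpy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        warnings.warn(f"listwise deletion removed {n0 - len(df)} patients "
                      "with missing covariates")
    encoded = pd.get_dummies(df, columns=[c for c in covariates
                                          if df[c].dtype == object],
                             drop_first=True, dtype=float)
    terms = [c for c in encoded.columns if c not in ("time", "event")]
    # scan risk_high first so a collinear clinical covariate is the one dropped
    terms.sort(key=lambda c: c != "risk_high")
    kept = []
    for c in terms:
        col = encoded[c].to_numpy(float)
        if np.std(col) == 0:
            warnings.warn(f"dropping constant covariate {c!r}")
            continue
        collinear = False
        for prev in kept:
            r = np.corrcoef(col, encoded[prev].to_numpy(float))[0, 1]
            if abs(r) > 1 - 1e-10:
                warnings.warn(f"dropping covariate {c!r}: collinear with {prev!r}")
                collinear = True
                break
        if not collinear:
            kept.append(c)
    rows = []
    for c in kept:
        cph = CoxPHFitter()
        cph.fit(encoded[["time", "event", c]], "time", "event")
        s = cph.summary.loc[c]
        rows.append({"term": c, "model": "univariate",
                     "hr": s["exp(coef)"], "ci_low": s["exp(coef) lower 95%"],
                     "ci_high": s["exp(coef) upper 95%"], "p": s["p"]})
    cph = CoxPHFitter()
    cph.fit(encoded[["time", "event"] + kept], "time", "event")
    for c in kept:
        s = cph.summary.loc[c]
        rows.append({"term": c, "model": "multivariable",
                     "hr": s["exp(coef)"], "ci_low": s["exp(coef) lower 95%"],
                     "ci_high": s["exp(coef) upper 95%"], "p": s["p"]})
    return pd.DataFrame(rows)
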