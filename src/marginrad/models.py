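"""Prognostic modelling chain: LASSO selection, survival models with
Harrell's C-index, 10-fold internal validation, Kaplan-Meier risk
stratification, time-dependent AUC, and the logistic micropapillary model.

The survival path is a Cox proportional-hazards fit with backward
stepwise pruning by AIC; exponentiated coefficients with 95% CIs are
reported as ratios.  (The study design this emulates is ambiguous about
proportional-hazards versus logistic modelling of overall survival; a
logistic-on-event-status variant is available via ``family="logistic"``.)
All randomized steps take explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV, lasso_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from .pipeline import MinMaxNormalizer

__all__ = [
    "ModelReport",
    "LassoSelector",
    "lasso_select",
    "harrell_c_index",
    "fit_survival_model",
    "internal_cv",
    "km_stratified",
    "time_dependent_auc",
    "MicropapillaryClassifier",
    "fit_mp_model",
]


@dataclass
class ModelReport:
    """Fitted coefficients and validation summaries for one modelling run."""

    model: str
    covariates: list[str]
    coefficients: pd.DataFrame | None = None
    c_index: float | None = None
    cv_c_index: float | None = None
    cv_per_fold: list[float] = field(default_factory=list)
    km_strata: dict = field(default_factory=dict)
    td_auc: dict = field(default_factory=dict)
    mp_auc: float | None = None
    mp_auc_ci: tuple[float, float] | None = None
    selected_features: list[str] = field(default_factory=list)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "covariates": self.covariates,
            "c_index": self.c_index,
            "cv_c_index": self.cv_c_index,
            "cv_per_fold": self.cv_per_fold,
            "mp_auc": self.mp_auc,
            "mp_auc_ci": list(self.mp_auc_ci) if self.mp_auc_ci else None,
            "selected_features": self.selected_features,
            "seed": self.seed,
            "config": self.config,
        }
        if self.coefficients is not None:
            out["coefficients"] = self.coefficients.to_dict(orient="index")
        if self.km_strata:
            out["km_strata"] = {
                str(k): {kk: vv for kk, vv in v.items() if kk not in ("km_low", "km_high")}
                for k, v in self.km_strata.items()
            }
        if self.td_auc:
            out["td_auc"] = {
                "times": list(np.asarray(self.td_auc["times"], dtype=float)),
                "auc": list(np.asarray(self.td_auc["auc"], dtype=float)),
            }
        return out


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------


def _cox_neg_log_partial_likelihood(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                                    beta: np.ndarray) -> float:
    """Breslow negative log partial likelihood, used as held-out deviance."""
    lp = X @ beta
    order = np.argsort(-time)  # descending time
    lp_ord = lp[order]
    # log cumulative sum of exp(lp) over the risk set (subjects with T >= t)
    mx = lp_ord.max() if len(lp_ord) else 0.0
    log_cum = np.log(np.cumsum(np.exp(lp_ord - mx))) + mx
    events_ord = event[order].astype(bool)
    return float(-(lp_ord[events_ord] - log_cum[events_ord]).sum())


class LassoSelector(BaseEstimator):
    """L1-penalized feature selection for survival, binary or linear outcomes.

    The penalty grid has ``n_alphas`` log-spaced values; the working
    penalty is chosen by ``folds``-fold cross-validation minimizing mean
    held-out deviance (negative partial likelihood for Cox, log loss for
    logistic, squared error for linear).

    Attributes (after ``fit``)
    --------------------------
    support_ : boolean mask of selected features
    selected_ : list of selected feature names
    alpha_ : chosen penalty
    path_ : DataFrame of coefficients along the penalty grid (features x alphas)
    """

    def __init__(self, family: str = "cox", n_alphas: int = 100, folds: int = 10,
                 seed: int = 0):
        self.family = family
        self.n_alphas = n_alphas
        self.folds = folds
        self.seed = seed

    def fit(self, X, y) -> "LassoSelector":
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns.astype(str))
        Xv = X.to_numpy(dtype=float)
        if self.family == "cox":
            self._fit_cox(Xv, y)
        elif self.family == "binary":
            self._fit_binary(Xv, np.asarray(y))
        elif self.family == "linear":
            self._fit_linear(Xv, np.asarray(y, dtype=float))
        else:
            raise ValueError(f"unknown family {self.family!r}")
        self.selected_ = [n for n, s in zip(self.feature_names_, self.support_) if s]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    # -- families -----------------------------------------------------------

    def _fit_cox(self, X: np.ndarray, y) -> None:
        time = np.asarray(y["time"], dtype=float)
        event = np.asarray(y["event"], dtype=float)
        if event.sum() == 0:
            raise ValueError("degenerate outcome: no events")
        y_struct = Surv.from_arrays(event=event.astype(bool), time=time)
        base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=self.n_alphas,
                                      alpha_min_ratio=0.01)
        base.fit(X, y_struct)
        alphas = np.asarray(base.alphas_)
        cv = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        dev = np.zeros((self.folds, len(alphas)))
        for i, (tr, te) in enumerate(cv.split(X)):
            if event[tr].sum() == 0 or event[te].sum() == 0:
                dev[i] = np.nan
                continue
            est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
            est.fit(X[tr], y_struct[tr])
            coefs = np.asarray(est.coef_)  # (p, n_alphas)
            for j in range(coefs.shape[1]):
                dev[i, j] = 2.0 * _cox_neg_log_partial_likelihood(
                    X[te], time[te], event[te], coefs[:, j]
                )
        mean_dev = np.nanmean(dev, axis=0)
        best = int(np.nanargmin(mean_dev))
        self.alpha_ = float(alphas[best])
        self.cv_deviance_ = pd.Series(mean_dev, index=alphas, name="mean_cv_deviance")
        coef_path = np.asarray(base.coef_)
        self.path_ = pd.DataFrame(coef_path, index=self.feature_names_, columns=alphas)
        self.coef_ = coef_path[:, best]
        self.support_ = self.coef_ != 0

    def _fit_binary(self, X: np.ndarray, y: np.ndarray) -> None:
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate outcome: single class")
        cv = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        est = LogisticRegressionCV(
            Cs=self.n_alphas, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", max_iter=2000, random_state=self.seed,
        )
        with warnings.catch_warnings():
            # scikit-learn 1.8+ announces the penalty->l1_ratios API migration
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(X, y)
        n = len(y)
        self.alpha_ = float(1.0 / (est.C_[0] * n))
        self.coef_ = est.coef_.ravel()
        self.support_ = self.coef_ != 0
        # refit the path on the full data for the selection trace
        coefs_paths = est.coefs_paths_[1].mean(axis=0)[:, :-1]  # (n_Cs, p), drop intercept
        alphas = 1.0 / (np.asarray(est.Cs_) * n)
        self.path_ = pd.DataFrame(coefs_paths.T, index=self.feature_names_, columns=alphas)
        self.cv_deviance_ = pd.Series(
            -2.0 * est.scores_[1].mean(axis=0), index=alphas, name="mean_cv_deviance"
        )

    def _fit_linear(self, X: np.ndarray, y: np.ndarray) -> None:
        alphas, coefs, _ = lasso_path(X, y, alphas=self.n_alphas, tol=1e-10)
        cv = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        dev = np.zeros((self.folds, len(alphas)))
        for i, (tr, te) in enumerate(cv.split(X)):
            _, fold_coefs, _ = lasso_path(X[tr], y[tr], alphas=alphas, tol=1e-10)
            pred = X[te] @ fold_coefs + y[tr].mean()
            dev[i] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
        mean_dev = dev.mean(axis=0)
        best = int(np.argmin(mean_dev))
        self.alpha_ = float(alphas[best])
        self.cv_deviance_ = pd.Series(mean_dev, index=alphas, name="mean_cv_deviance")
        self.path_ = pd.DataFrame(coefs, index=self.feature_names_, columns=alphas)
        self.coef_ = coefs[:, best]
        self.support_ = self.coef_ != 0

    def select_at(self, alpha: float) -> list[str]:
        """Nonzero features at the grid penalty nearest to ``alpha``."""
        col = self.path_.columns[np.argmin(np.abs(self.path_.columns.to_numpy() - alpha))]
        return list(self.path_.index[self.path_[col] != 0])


def lasso_select(X, y, family: str = "cox", folds: int = 10, seed: int = 0) -> LassoSelector:
    """Fit a :class:`LassoSelector` and return it (selected names in ``.selected_``)."""
    return LassoSelector(family=family, folds=folds, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# Survival modelling
# ---------------------------------------------------------------------------


def harrell_c_index(time, event, risk) -> float:
    """Harrell's concordance: concordant pairs / comparable pairs, ties at 0.5."""
    result = concordance_index_censored(
        np.asarray(event, dtype=bool), np.asarray(time, dtype=float),
        np.asarray(risk, dtype=float),
    )
    return float(result[0])


def _backward_stepwise_cox(df: pd.DataFrame, covariates: list[str],
                           duration_col: str, event_col: str) -> tuple[CoxPHFitter, list[str]]:
    """Backward elimination by AIC on a Cox PH model."""
    current = list(covariates)

    def fit(cols: list[str]) -> CoxPHFitter:
        cph = CoxPHFitter()
        cph.fit(df[cols + [duration_col, event_col]], duration_col=duration_col,
                event_col=event_col)
        return cph

    best_model = fit(current)
    best_aic = best_model.AIC_partial_
    improved = True
    while improved and len(current) > 1:
        improved = False
        for col in list(current):
            trial = [c for c in current if c != col]
            try:
                m = fit(trial)
            except Exception:  # noqa: BLE001 - dropped column may break convergence
                continue
            if m.AIC_partial_ < best_aic - 1e-9:
                best_aic, best_model, current = m.AIC_partial_, m, trial
                improved = True
                break
    return best_model, current


def fit_survival_model(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    stepwise: bool = True,
    family: str = "cox",
) -> ModelReport:
    """Proportional-hazards fit (optionally backward-stepwise by AIC) with
    exponentiated coefficients, 95% CIs and Harrell's C-index.

    ``family="logistic"`` instead fits event status by logistic
    regression (stepwise by AIC) and reports odds ratios; the linear
    predictor still yields a C-index against the censored times.
    """
    covariates = list(covariates)
    if cohort[event_col].sum() < 10:
        raise ValueError("need >= 10 events to fit a survival model")
    if family == "cox":
        if stepwise:
            model, kept = _backward_stepwise_cox(cohort, covariates, duration_col, event_col)
        else:
            model = CoxPHFitter()
            model.fit(cohort[covariates + [duration_col, event_col]],
                      duration_col=duration_col, event_col=event_col)
            kept = covariates
        summ = model.summary
        coef_table = pd.DataFrame({
            "coef": summ["coef"],
            "ratio": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        })
        risk = model.predict_partial_hazard(cohort[kept]).to_numpy().ravel()
    elif family == "logistic":
        import statsmodels.api as sm

        kept = list(covariates)
        model = sm.Logit(cohort[event_col], sm.add_constant(cohort[kept])).fit(disp=0)
        if stepwise:
            best_aic = model.aic
            improved = True
            while improved and len(kept) > 1:
                improved = False
                for col in list(kept):
                    trial = [c for c in kept if c != col]
                    m = sm.Logit(cohort[event_col], sm.add_constant(cohort[trial])).fit(disp=0)
                    if m.aic < best_aic - 1e-9:
                        best_aic, model, kept = m.aic, m, trial
                        improved = True
                        break
        params = model.params.drop("const")
        ci = model.conf_int().drop("const")
        coef_table = pd.DataFrame({
            "coef": params,
            "ratio": np.exp(params),
            "ci_lower": np.exp(ci[0]),
            "ci_upper": np.exp(ci[1]),
            "p": model.pvalues.drop("const"),
        })
        risk = (cohort[kept].to_numpy(dtype=float) @ params.to_numpy())
    else:
        raise ValueError(f"unknown family {family!r}")

    c_index = harrell_c_index(cohort[duration_col], cohort[event_col], risk)
    return ModelReport(
        model=family, covariates=kept, coefficients=coef_table, c_index=c_index,
        config={"stepwise": stepwise, "duration_col": duration_col, "event_col": event_col},
    )


def internal_cv(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    folds: int = 10,
    seed: int = 0,
    normalize_columns: Sequence[str] | None = None,
    stepwise: bool = False,
) -> ModelReport:
    """10-fold cross-validated C-index of a Cox model.

    Folds are stratified on the event indicator so every training fold
    carries events.  Normalization (when requested) is refit on each
    training fold and applied to the held-out fold.  Held-out linear
    predictors are pooled into a single C-index; per-fold values are also
    reported.
    """
    covariates = list(covariates)
    if cohort[event_col].sum() < folds:
        raise ValueError("need at least one event per fold")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    event = cohort[event_col].to_numpy()
    pooled_risk = np.zeros(len(cohort))
    per_fold = []
    for tr_idx, te_idx in cv.split(cohort, event):
        train = cohort.iloc[tr_idx].copy()
        test = cohort.iloc[te_idx].copy()
        if normalize_columns:
            norm = MinMaxNormalizer(columns=list(normalize_columns)).fit(train)
            train = norm.transform(train)
            test = norm.transform(test)
        report = fit_survival_model(train, covariates, duration_col, event_col,
                                    stepwise=stepwise)
        beta = report.coefficients["coef"].reindex(report.covariates).to_numpy()
        risk = test[report.covariates].to_numpy(dtype=float) @ beta
        pooled_risk[te_idx] = risk
        if event[te_idx].sum() > 0:
            per_fold.append(harrell_c_index(test[duration_col], test[event_col], risk))
    pooled_c = harrell_c_index(cohort[duration_col], cohort[event_col], pooled_risk)
    return ModelReport(
        model="cox-cv", covariates=covariates, cv_c_index=pooled_c, cv_per_fold=per_fold,
        seed=seed, config={"folds": folds, "normalized": bool(normalize_columns)},
    )


def km_stratified(
    cohort: pd.DataFrame,
    risk: np.ndarray,
    stratum_col: str,
    duration_col: str = "time",
    event_col: str = "event",
    min_stratum: int = 10,
) -> dict:
    """Kaplan-Meier curves and log-rank tests per stratum, split at the
    stratum median of the risk score (low vs high risk).

    Strata with fewer than ``min_stratum`` subjects are skipped with a
    warning.  A stratum where the median split leaves one group empty
    (constant risk) reports chi2 = 0, p = 1.
    """
    risk = np.asarray(risk, dtype=float)
    out: dict = {}
    for stratum, grp in cohort.groupby(stratum_col):
        idx = cohort.index.get_indexer(grp.index)
        if len(grp) < min_stratum:
            warnings.warn(f"stratum {stratum!r} has {len(grp)} subjects; skipped")
            continue
        r = risk[idx]
        high = r > np.median(r)
        low = ~high
        entry: dict = {"n": len(grp), "n_high": int(high.sum()), "n_low": int(low.sum())}
        if high.sum() == 0 or low.sum() == 0:
            entry.update(chi2=0.0, p=1.0, km_low=None, km_high=None)
            out[stratum] = entry
            continue
        km_low, km_high = KaplanMeierFitter(), KaplanMeierFitter()
        km_low.fit(grp[duration_col][low], grp[event_col][low], label="low risk")
        km_high.fit(grp[duration_col][high], grp[event_col][high], label="high risk")
        lr = logrank_test(
            grp[duration_col][low], grp[duration_col][high],
            event_observed_A=grp[event_col][low], event_observed_B=grp[event_col][high],
        )
        entry.update(chi2=float(lr.test_statistic), p=float(lr.p_value),
                     km_low=km_low, km_high=km_high)
        out[stratum] = entry
    return out


def time_dependent_auc(
    validation: pd.DataFrame,
    risk: np.ndarray,
    times: np.ndarray,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[np.ndarray, float]:
    """Cumulative-case / dynamic-control AUC(t) with IPCW weights from the
    validation cohort's Kaplan-Meier censoring estimator.

    Returns ``(auc_series, mean_auc)`` over the time grid.
    """
    y = Surv.from_arrays(
        event=validation[event_col].to_numpy(dtype=bool),
        time=validation[duration_col].to_numpy(dtype=float),
    )
    times = np.asarray(times, dtype=float)
    max_time = validation[duration_col].to_numpy().max()
    times = times[(times > 0) & (times < max_time)]
    events_before = validation[
        (validation[event_col] == 1) & (validation[duration_col] <= times.max())
    ]
    if len(events_before) == 0:
        raise ValueError("no events inside the evaluation grid")
    auc, mean_auc = cumulative_dynamic_auc(y, y, np.asarray(risk, dtype=float), times)
    return auc, float(mean_auc)


# ---------------------------------------------------------------------------
# Micropapillary model
# ---------------------------------------------------------------------------


class MicropapillaryClassifier(BaseEstimator):
    """LASSO-selected logistic model for the micropapillary label.

    ``fit`` normalizes the candidate features to [0, 1], runs L1-penalized
    logistic selection, then fits an unpenalized logistic model on the
    selected features.  An empty selection degrades to an intercept-only
    model (predicted probability = training prevalence).
    """

    def __init__(self, folds: int = 10, seed: int = 0):
        self.folds = folds
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "MicropapillaryClassifier":
        y = np.asarray(y)
        self.normalizer_ = MinMaxNormalizer(columns=list(X.columns)).fit(X)
        Xn = self.normalizer_.transform(X)
        self.selector_ = LassoSelector(family="binary", folds=self.folds, seed=self.seed)
        self.selector_.fit(Xn, y)
        self.selected_ = self.selector_.selected_
        if self.selected_:
            self.model_ = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized
            self.model_.fit(Xn[self.selected_], y)
        else:
            self.model_ = None
            self.prevalence_ = float(y.mean())
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xn = self.normalizer_.transform(X)
        if self.model_ is None:
            p = np.full(len(X), self.prevalence_)
            return np.column_stack([1 - p, p])
        return self.model_.predict_proba(Xn[self.selected_])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _bootstrap_auc_ci(y: np.ndarray, score: np.ndarray, seed: int,
                      n_boot: int = 1000) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        aucs.append(roc_auc_score(y[idx], score[idx]))
    return float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))


def fit_mp_model(
    cohort: pd.DataFrame,
    candidate_features: Sequence[str],
    mp_col: str = "mp",
    split: float = 0.7,
    seed: int = 0,
) -> ModelReport:
    """Split-data validated logistic model of the micropapillary label.

    LASSO selection and the logistic fit use the training split only; the
    reported AUC (with 95% bootstrap CI) is computed on the held-out
    split.  The split is stratified on the label so both classes appear
    on both sides.
    """
    candidate_features = list(candidate_features)
    y = cohort[mp_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("micropapillary label has a single class")
    train_idx, test_idx = train_test_split(
        np.arange(len(cohort)), train_size=split, random_state=seed, stratify=y
    )
    clf = MicropapillaryClassifier(seed=seed).fit(
        cohort.iloc[train_idx][candidate_features], y[train_idx]
    )
    score = clf.predict_proba(cohort.iloc[test_idx][candidate_features])[:, 1]
    if len(np.unique(score)) > 1:
        auc = float(roc_auc_score(y[test_idx], score))
        ci = _bootstrap_auc_ci(y[test_idx], score, seed=seed)
    else:
        auc, ci = 0.5, (0.5, 0.5)
    coef_table = None
    if clf.selected_:
        params = pd.Series(clf.model_.coef_.ravel(), index=clf.selected_)
        coef_table = pd.DataFrame({"coef": params, "ratio": np.exp(params)})
    return ModelReport(
        model="mp-logistic", covariates=candidate_features, coefficients=coef_table,
        selected_features=clf.selected_, mp_auc=auc, mp_auc_ci=ci, seed=seed,
        config={"split": split, "ci_method": "bootstrap (1000 resamples)"},
    )
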