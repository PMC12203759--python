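"""Covariate-adjusted regression of HRQoL/well-being on profile transitions.

Modal profile assignments at the two timepoints define transition categories
(schoolday profile -> weekend profile). Categories observed in fewer than 1%
of participants are excluded (their participants are dropped, never
reassigned); a merge map can pool sparse schoolday profiles first (e.g.
"Fair" and "Poor" into "Fair-or-Poor"). Outcomes are regressed by OLS on
category indicators relative to a reference category (stable
Excellent->Excellent), adjusted for age, sex, BMI z-score and maternal
education. Missing covariates (BMI z, maternal education) are handled by
chained-equations multiple imputation — predictive mean matching for the
continuous BMI z-score, a Bayesian logistic draw for the binary education
indicator — and the per-imputation OLS fits are pooled by Rubin's rules with
Barnard-Rubin adjusted degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ARROW = "->"
COVARIATE_COLUMNS = ("age", "sex", "bmi_z", "maternal_education")
IMPUTED_COLUMNS = ("bmi_z", "maternal_education")

__all__ = [
    "TransitionCategories",
    "build_transition_categories",
    "impute_covariates",
    "TransitionRegression",
    "TransitionRegressionResults",
    "fit_transition_regression",
]


@dataclass
class TransitionCategories:
    """Per-participant transition-category labels after merging/exclusion.

    ``labels`` has one entry per input participant; excluded participants
    (rare transitions) carry None. ``categories`` lists retained labels with
    the reference first.
    """

    labels: pd.Series
    categories: list[str]
    reference: str
    counts: pd.Series

    @property
    def included(self) -> pd.Series:
        return self.labels.notna()


def transition_label(school: str, weekend: str) -> str:
    return f"{school}{ARROW}{weekend}"


def build_transition_categories(
    modal_school,
    modal_weekend,
    min_freq_pct: float = 1.0,
    merge_map: dict[str, str] | None = None,
    reference: str | None = None,
) -> TransitionCategories:
    """Tally transition pairs, merge, and drop categories below 1%.

    ``merge_map`` renames schoolday profiles before frequencies are counted
    (e.g. ``{"Fair": "Fair-or-Poor", "Poor": "Fair-or-Poor"}``). Pairs with
    frequency below ``min_freq_pct`` of n are excluded; their participants
    get a None label. The reference defaults to "Excellent->Excellent" and
    must be present among retained categories.
    """
    school = pd.Series(modal_school).astype(str)
    weekend = pd.Series(modal_weekend).astype(str).set_axis(school.index)
    if merge_map:
        school = school.replace(merge_map)
    labels = school + ARROW + weekend
    n = len(labels)
    counts = labels.value_counts()
    keep = counts[counts >= min_freq_pct / 100.0 * n]
    if reference is None:
        reference = transition_label("Excellent", "Excellent")
    if reference not in keep.index:
        raise ValueError(f"reference category {reference!r} absent after exclusion")
    out = labels.where(labels.isin(keep.index), None)
    ordered = [reference] + sorted(c for c in keep.index if c != reference)
    return TransitionCategories(labels=out, categories=ordered, reference=reference, counts=counts)


# ------------------------------------------------------------------ MI ----


def _pmm_draw(y_obs, X_obs, X_mis, rng, k_donors=5):
    """Predictive mean matching with a Bayesian regression parameter draw."""
    n_obs, p = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    df = max(n_obs - p, 1)
    sigma2 = resid @ resid / stats.chi2.rvs(df, random_state=rng)
    cov = sigma2 * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="svd")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    out = np.empty(len(X_mis))
    for i, pm in enumerate(pred_mis):
        idx = np.argsort(np.abs(pred_obs - pm))[:k_donors]
        out[i] = y_obs[rng.choice(idx)]
    return out


def _logistic_draw(y_obs, X_obs, X_mis, rng):
    """Binary draw from a logistic model with posterior parameter perturbation."""
    try:
        fit = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
        beta = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
        beta_star = rng.multivariate_normal(beta, cov, method="svd")
        p = 1.0 / (1.0 + np.exp(-(X_mis @ beta_star)))
    except Exception:  # separation or non-convergence: marginal draw
        p = np.full(len(X_mis), y_obs.mean())
    return (rng.random(len(X_mis)) < p).astype(float)


def impute_covariates(
    records: pd.DataFrame, m: int = 5, seed: int | None = None, n_cycles: int = 10, k_donors: int = 5
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation of BMI z and maternal education.

    Missingness is allowed only in ``bmi_z`` (continuous; imputed by
    predictive mean matching with ``k_donors`` donors) and
    ``maternal_education`` (binary; imputed by a logistic-regression draw).
    Age and sex must be complete and act as predictors. Returns ``m``
    completed copies; with no missing values these are identical to the
    input. Deterministic given ``seed``.
    """
    df = records.copy()
    for col in COVARIATE_COLUMNS:
        if col not in df:
            raise ValueError(f"missing covariate column {col!r}")
    for col in ("age", "sex"):
        if df[col].isna().any():
            raise ValueError(f"{col} must be complete")
    for col in IMPUTED_COLUMNS:
        if df[col].isna().all():
            raise ValueError(f"{col} is entirely missing; cannot impute")
    miss = {col: df[col].isna().to_numpy() for col in IMPUTED_COLUMNS}
    if not any(v.any() for v in miss.values()):
        return [df.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    out = []
    base = df[list(COVARIATE_COLUMNS)].to_numpy(float)
    for _ in range(m):
        work = base.copy()
        # initial fill: random draws from the observed values
        for j, col in enumerate(COVARIATE_COLUMNS):
            mk = miss.get(col)
            if mk is not None and mk.any():
                obs = work[~mk, j]
                work[mk, j] = rng.choice(obs, size=mk.sum())
        for _cycle in range(n_cycles):
            for col in IMPUTED_COLUMNS:
                j = COVARIATE_COLUMNS.index(col)
                mk = miss[col]
                if not mk.any():
                    continue
                others = [jj for jj in range(work.shape[1]) if jj != j]
                X = np.column_stack([np.ones(len(work)), work[:, others]])
                if col == "bmi_z":
                    work[mk, j] = _pmm_draw(work[~mk, j], X[~mk], X[mk], rng, k_donors)
                else:
                    work[mk, j] = _logistic_draw(work[~mk, j], X[~mk], X[mk], rng)
        comp = df.copy()
        comp[list(COVARIATE_COLUMNS)] = work
        out.append(comp)
    return out


# ------------------------------------------------------------- regression


class TransitionRegression:
    """OLS of an outcome on transition-category indicators plus covariates.

    Built from a participant table with the outcome column, a transition
    label column (None = excluded) and the four covariates. ``fit`` imputes
    missing covariates ``m`` times and pools by Rubin's rules.
    """

    def __init__(
        self,
        outcome: pd.Series,
        categories: TransitionCategories,
        covariates: pd.DataFrame,
    ):
        n = len(outcome)
        if len(categories.labels) != n or len(covariates) != n:
            raise ValueError("outcome, categories and covariates must align")
        keep = categories.included.to_numpy() & outcome.notna().to_numpy()
        self.outcome = pd.Series(np.asarray(outcome, float)[keep]).reset_index(drop=True)
        self.labels = categories.labels[keep].reset_index(drop=True)
        self.covariates = covariates.loc[keep, list(COVARIATE_COLUMNS)].reset_index(drop=True)
        self.categories = categories
        self.reference = categories.reference
        self.category_terms = [c for c in categories.categories if c != self.reference]
        if not (self.labels == self.reference).any():
            raise ValueError("no reference-category participants with outcome data")

    def _design(self, covariates: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame({"const": np.ones(len(self.labels))})
        for cat in self.category_terms:
            X[cat] = (self.labels == cat).astype(float)
        for col in COVARIATE_COLUMNS:
            X[col] = covariates[col].to_numpy(float)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name the offending columns for the error message
            bad = []
            cols = list(X.columns)
            arr = X.to_numpy()
            for j in range(1, len(cols)):
                if np.linalg.matrix_rank(arr[:, : j + 1]) == np.linalg.matrix_rank(arr[:, :j]):
                    bad.append(cols[j])
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        return X

    def fit(self, m: int = 5, seed: int | None = None) -> "TransitionRegressionResults":
        """Impute covariates m times, fit OLS per copy, pool by Rubin's rules."""
        completed = impute_covariates(self.covariates, m=m, seed=seed)
        params, covs = [], []
        exog_names = None
        nobs = kparam = None
        for comp in completed:
            X = self._design(comp)
            fit = sm.OLS(self.outcome, X).fit()
            params.append(np.asarray(fit.params))
            covs.append(np.asarray(fit.cov_params()))
            exog_names = list(X.columns)
            nobs, kparam = int(fit.nobs), X.shape[1]
        params = np.vstack(params)
        covs = np.stack(covs)
        qbar = params.mean(axis=0)
        ubar = covs.mean(axis=0)
        if m > 1:
            bvar = np.cov(params.T, ddof=1)
            bdiag = params.var(axis=0, ddof=1)
        else:
            bvar = np.zeros((params.shape[1], params.shape[1]))
            bdiag = np.zeros(params.shape[1])
        tdiag = np.diag(ubar) + (1 + 1 / m) * bdiag
        # Barnard-Rubin degrees of freedom
        nu_com = nobs - kparam
        dfs = np.empty_like(qbar)
        for j in range(len(qbar)):
            if bdiag[j] <= 0:
                dfs[j] = nu_com
                continue
            lam = (1 + 1 / m) * bdiag[j] / tdiag[j]
            df_old = (m - 1) / lam**2
            df_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
            dfs[j] = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        return TransitionRegressionResults(
            model=self,
            params=pd.Series(qbar, index=exog_names),
            bse=pd.Series(np.sqrt(tdiag), index=exog_names),
            df=pd.Series(dfs, index=exog_names),
            m=m,
            within=pd.Series(np.diag(ubar), index=exog_names),
            between=pd.Series(bdiag, index=exog_names),
            nobs=nobs,
        )


@dataclass
class TransitionRegressionResults:
    """Rubin-pooled regression estimates with t-based inference."""

    model: TransitionRegression
    params: pd.Series
    bse: pd.Series
    df: pd.Series
    m: int
    within: pd.Series
    between: pd.Series
    nobs: int

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2, self.df)
        return pd.DataFrame(
            {"lower": self.params - tcrit * self.bse, "upper": self.params + tcrit * self.bse}
        )

    def effect_table(self) -> pd.DataFrame:
        """Category rows only, with the reference pinned at B = 0."""
        ci = self.conf_int()
        rows = [
            {
                "category": self.model.reference,
                "B": 0.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "reference": True,
            }
        ]
        for cat in self.model.category_terms:
            rows.append(
                {
                    "category": cat,
                    "B": self.params[cat],
                    "ci_low": ci.loc[cat, "lower"],
                    "ci_high": ci.loc[cat, "upper"],
                    "p": self.pvalues[cat],
                    "reference": False,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ci = self.conf_int()
        df = pd.DataFrame(
            {
                "B": self.params,
                "SE": self.bse,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
                "df": self.df,
                "p": self.pvalues,
            }
        )
        head = (
            f"Transition regression (n = {self.nobs}, m = {self.m} imputations, "
            f"reference = {self.model.reference})\n"
        )
        return head + df.round(4).to_string()


def fit_transition_regression(
    outcome: pd.Series,
    categories: TransitionCategories,
    covariates: pd.DataFrame,
    m: int = 5,
    seed: int | None = None,
) -> TransitionRegressionResults:
    """One-call wrapper: build the model and fit with pooled MI."""
    return TransitionRegression(outcome, categories, covariates).fit(m=m, seed=seed)
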