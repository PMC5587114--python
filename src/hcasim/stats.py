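"""Agreement and variance-decomposition statistics for method validation.

Implements the validation toolkit used to compare measurement routes
against each other and to decompose sources of variation in read rate,
activity and temperature:

* ICC(1,k): one-way random-effects, average-of-k-measurements intraclass
  correlation, ``(BMS - WMS) / BMS`` (ICC(A,k), the two-way absolute
  agreement form, is available as an option).
* Bland-Altman bias and 95% limits of agreement.
* OLS and a single-random-intercept linear mixed model; the mixed model is
  estimated by REML with the variance ratio profiled out (1-D bounded
  optimization, GLS inner solve).
* A log-link negative binomial count regression (for over-dispersed
  transition counts).
* Paired two-sided t-test.
* The implantation-site scoring rubric (read-frequency / ICC / R^2 bands)
  and light/dark phase summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
import statsmodels.api as sm


# --------------------------------------------------------------------------
# result containers

@dataclass
class ICCResult:
    icc: float
    bms: float
    wms: float
    n: int
    k: int
    method: str = "icc1k"

    def defined(self) -> bool:
        return np.isfinite(self.icc)


@dataclass
class BAResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class RegressionFit:
    label: str
    terms: dict  # name -> {"estimate", "se", "p"}
    sigma2: float
    tau2: Optional[float] = None
    group: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def estimate(self, name: str) -> float:
        return self.terms[name]["estimate"]

    def se(self, name: str) -> float:
        return self.terms[name]["se"]

    def to_dict(self) -> dict:
        out = {"label": self.label, "sigma2": self.sigma2, "terms": self.terms}
        if self.tau2 is not None:
            out["tau2"] = self.tau2
            out["group"] = self.group
        out.update(self.extra)
        return out


# --------------------------------------------------------------------------
# intraclass correlation

def icc_1k(matrix) -> ICCResult:
    """ICC(1,k): agreement of the average of k measurements per subject,
    from the one-way random-effects ANOVA decomposition."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x measurements)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 measurements")
    if np.isnan(m).any():
        raise ValueError("ICC requires a complete matrix (no missing cells)")
    row_means = m.mean(axis=1)
    grand = m.mean()
    bms = k * ((row_means - grand) ** 2).sum() / (n - 1)
    wms = ((m - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if bms <= 0 and wms <= 0:
        return ICCResult(np.nan, bms, wms, n, k)
    icc = np.nan if bms == 0 else (bms - wms) / bms
    return ICCResult(float(icc), float(bms), float(wms), n, k)


def icc_ak(matrix) -> ICCResult:
    """ICC(A,k): two-way random-effects absolute-agreement, average of k."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 measurements")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    grand = m.mean()
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((m - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    icc = np.nan if denom == 0 else (msr - mse) / denom
    return ICCResult(float(icc), float(msr), float(mse), n, k, method="icc_ak")


# --------------------------------------------------------------------------
# Bland-Altman

def bland_altman(x, y) -> BAResult:
    """Bias and 1.96-SD limits of agreement of paired differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BAResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, len(x))


# --------------------------------------------------------------------------
# design matrices

def build_design(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + terms; categorical columns are treatment-coded with the
    alphabetically first level as reference."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in terms:
        if term not in df.columns:
            raise ValueError(f"term {term!r} not in data")
        col = df[term]
        if col.dtype.kind in "ifub" and col.dtype.kind != "b":
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(map(str, col.astype(str).unique()))
            vals = col.astype(str).to_numpy()
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{term}[{lev}]")
    X = np.column_stack(cols)
    # locate the first aliased column, if any
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, :j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"design is rank deficient: term {names[j]!r} is aliased")
    return X, names


def _wald_p(est: np.ndarray, se: np.ndarray, df_resid: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    return 2 * sps.t.sf(np.abs(t), df_resid)


# --------------------------------------------------------------------------
# ordinary least squares

def fit_ols(df: pd.DataFrame, response: str, terms: Sequence[str],
            label: str = "ols") -> RegressionFit:
    """Least-squares fit with classical standard errors."""
    y = df[response].to_numpy(dtype=float)
    X, names = build_design(df, terms)
    res = sm.OLS(y, X).fit()
    terms_out = {
        name: {"estimate": float(res.params[i]), "se": float(res.bse[i]),
               "p": float(res.pvalues[i])}
        for i, name in enumerate(names)
    }
    return RegressionFit(label, terms_out, float(res.scale),
                         extra={"r2": float(res.rsquared) if res.df_model > 0 else 0.0})


# --------------------------------------------------------------------------
# single random-intercept linear mixed model (profiled REML)

def _reml_parts(X, y, group_idx, n_groups):
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    S1 = np.zeros((n_groups, p))
    sy = np.zeros(n_groups)
    np.add.at(S1, group_idx, X)
    np.add.at(sy, group_idx, y)
    m = np.bincount(group_idx, minlength=n_groups).astype(float)
    return XtX, Xty, yty, S1, sy, m


def _reml_criterion(lam, parts, n, p):
    XtX, Xty, yty, S1, sy, m = parts
    w = lam / (1.0 + lam * m)
    XtVX = XtX - (S1 * w[:, None]).T @ S1
    XtVy = Xty - S1.T @ (w * sy)
    ytVy = yty - float(w @ (sy * sy))
    try:
        L = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - float(beta @ XtVy), 1e-300)
    sigma2 = rss / (n - p)
    logdet_V = float(np.log1p(lam * m).sum())
    logdet_XtVX = 2.0 * float(np.log(np.diag(L)).sum())
    crit = (n - p) * np.log(sigma2) + logdet_V + logdet_XtVX
    return crit, (beta, sigma2, XtVX)


def fit_random_intercept(df: pd.DataFrame, response: str, fixed_terms: Sequence[str],
                         group: str, label: str = "mixed") -> RegressionFit:
    """REML fit of a linear mixed model with one random intercept.

    The ratio lambda = tau^2 / sigma^2 is profiled out by bounded 1-D
    optimization on log(lambda); fixed effects come from the GLS solve at
    the optimum. With a single group the model degenerates and an OLS fit
    is returned with a warning flag in the label.
    """
    y = df[response].to_numpy(dtype=float)
    keep = np.isfinite(y)
    df = df.loc[keep].reset_index(drop=True)
    y = y[keep]
    X, names = build_design(df, fixed_terms)
    n, p = X.shape
    codes, uniques = pd.factorize(df[group].astype(str))
    n_groups = len(uniques)
    if n_groups < 2:
        fit = fit_ols(df, response, fixed_terms, label=label + "+ols_fallback")
        fit.tau2 = 0.0
        fit.group = group
        fit.extra["warning"] = "single group: fell back to OLS"
        return fit
    parts = _reml_parts(X, y, codes, n_groups)

    def obj(u):
        return _reml_criterion(np.exp(u), parts, n, p)[0]

    res = optimize.minimize_scalar(obj, bounds=(-15.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    crit0, sol0 = _reml_criterion(0.0, parts, n, p)
    if crit0 <= res.fun:
        lam = 0.0
        crit, sol = crit0, sol0
    else:
        lam = float(np.exp(res.x))
        crit, sol = _reml_criterion(lam, parts, n, p)
    beta, sigma2, XtVX = sol
    cov = np.linalg.inv(XtVX) * sigma2
    se = np.sqrt(np.diag(cov))
    pvals = _wald_p(beta, se, n - p)
    terms_out = {
        name: {"estimate": float(beta[i]), "se": float(se[i]), "p": float(pvals[i])}
        for i, name in enumerate(names)
    }
    return RegressionFit(label, terms_out, float(sigma2), tau2=float(lam * sigma2),
                         group=group, extra={"reml_criterion": float(crit),
                                             "n_groups": n_groups})


# --------------------------------------------------------------------------
# negative binomial count regression

def fit_negbin(df: pd.DataFrame, response: str, terms: Sequence[str],
               label: str = "negbin") -> RegressionFit:
    """Log-link negative binomial (NB2) maximum-likelihood fit."""
    y = df[response].to_numpy()
    yf = np.asarray(y, dtype=float)
    if np.any(yf < 0) or np.any(yf != np.round(yf)):
        raise ValueError("negative binomial response must be non-negative integers")
    X, names = build_design(df, terms)
    model = sm.NegativeBinomial(yf, X)
    res = model.fit(disp=0, maxiter=500)
    terms_out = {
        name: {"estimate": float(res.params[i]), "se": float(res.bse[i]),
               "p": float(res.pvalues[i])}
        for i, name in enumerate(names)
    }
    alpha = float(res.params[-1])
    return RegressionFit(label, terms_out, sigma2=np.nan,
                         extra={"alpha": alpha, "llf": float(res.llf)})


# --------------------------------------------------------------------------
# paired t-test

def paired_t(x1, x2) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or len(x1) < 2:
        raise ValueError("need equal-length 1-D vectors with n >= 2")
    d = x1 - x2
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    res = sps.ttest_rel(x1, x2)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# implantation-site scoring rubric

_READ_FREQ_EDGES = (0.3, 0.4, 0.6, 0.75)
_ICC_EDGES = (0.0, 0.5, 0.7, 0.9)
_R2_EDGES = (0.3, 0.5, 0.7, 0.9)


def _band_score(value: float, edges: tuple) -> int:
    """Map a metric into its 1-5 band; half-open [lower, upper) bands so a
    boundary value belongs to the band it opens."""
    return 1 + int(np.searchsorted(edges, value, side="right"))


@dataclass
class RubricScores:
    scores: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"criterion": k, "score": v} for k, v in self.scores.items()])


def rubric_scores(read_freq_hz: Optional[float] = None,
                  icc_tracking: Optional[float] = None,
                  r2_sideview: Optional[float] = None,
                  implant_issue_count: Optional[int] = None,
                  ease_of_implantation: Optional[int] = None) -> RubricScores:
    """Score site-selection criteria on their 1-5 bands."""
    scores: dict = {}
    if read_freq_hz is not None:
        scores["read_frequency"] = _band_score(read_freq_hz, _READ_FREQ_EDGES)
    if icc_tracking is not None:
        scores["tracking_icc"] = _band_score(icc_tracking, _ICC_EDGES)
    if r2_sideview is not None:
        scores["sideview_r2"] = _band_score(r2_sideview, _R2_EDGES)
    if implant_issue_count is not None:
        if implant_issue_count < 0:
            raise ValueError("implant_issue_count must be >= 0")
        scores["implantation_integrity"] = max(1, 5 - int(implant_issue_count))
    if ease_of_implantation is not None:
        if not 1 <= ease_of_implantation <= 5:
            raise ValueError("ease_of_implantation must be 1..5")
        scores["ease_of_implantation"] = int(ease_of_implantation)
    return RubricScores(scores)


# --------------------------------------------------------------------------
# light/dark summaries

@dataclass
class LightDarkSummary:
    per_animal: pd.DataFrame  # animal_id, light_mean, dark_mean, ratio, difference
    cage_light_mean: float
    cage_dark_mean: float
    cage_ratio: Optional[float]
    cage_difference: float

    @property
    def mean_ratio(self) -> Optional[float]:
        r = self.per_animal["ratio"].dropna()
        return float(r.mean()) if len(r) else None

    @property
    def ratio_sd(self) -> Optional[float]:
        r = self.per_animal["ratio"].dropna()
        return float(r.std(ddof=1)) if len(r) > 1 else None


def light_dark_summary(bins: pd.DataFrame, value_col: str) -> LightDarkSummary:
    """Phase means, dark - light differences and dark:light ratios from a
    phase-labelled windowed series (per animal and cage level)."""
    if not {"animal_id", "phase", value_col} <= set(bins.columns):
        raise ValueError(f"bins must have animal_id, phase and {value_col!r} columns")
    rows = []
    for aid, sub in bins.groupby("animal_id"):
        lm = sub.loc[sub["phase"] == "light", value_col].mean()
        dm = sub.loc[sub["phase"] == "dark", value_col].mean()
        ratio = dm / lm if lm not in (0,) and np.isfinite(lm) and lm != 0 else np.nan
        rows.append({"animal_id": aid, "light_mean": lm, "dark_mean": dm,
                     "ratio": ratio, "difference": dm - lm})
    per_animal = pd.DataFrame(rows)
    lmean = float(per_animal["light_mean"].mean())
    dmean = float(per_animal["dark_mean"].mean())
    cage_ratio = dmean / lmean if lmean != 0 else None
    return LightDarkSummary(per_animal, lmean, dmean, cage_ratio, dmean - lmean)
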