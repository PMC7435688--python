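"""Encoder/converter classification and stool-metabolite association models.

A sample is an *encoder* when any cluster of the sterol-dehydrogenase family
is detected in its metagenome, and a *converter* when coprostanol is detected
in its metabolome. This module provides the 2x2 odds-ratio analysis linking
the two, the log10 + pseudo-count z-score transform applied to metabolite
abundances, and the regression machinery (OLS, logistic, random-intercept
linear for repeated measures) used to relate encoder status to metabolite
levels with age/sex/antibiotic/disease covariates, plus Benjamini-Hochberg
multiple-testing adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "RegressionResult",
    "SeparationError",
    "classify_samples",
    "odds_ratio",
    "transform_metabolite",
    "build_design",
    "fit_linear",
    "fit_logistic",
    "fit_random_intercept",
    "adjust_bh",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate due to complete separation."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (encoder, converter) cross-classification.

    ``a`` = encoder & converter, ``b`` = encoder & non-converter,
    ``c`` = non-encoder & converter, ``d`` = non-encoder & non-converter.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, encoder, converter) -> "ContingencyTable":
        enc = np.asarray(encoder, dtype=bool)
        con = np.asarray(converter, dtype=bool)
        if enc.shape != con.shape:
            raise ValueError("encoder and converter vectors differ in length")
        return cls(
            a=int(np.sum(enc & con)),
            b=int(np.sum(enc & ~con)),
            c=int(np.sum(~enc & con)),
            d=int(np.sum(~enc & ~con)),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str
    correction_applied: bool = False


@dataclass
class RegressionResult:
    """Coefficients and inference from a fitted regression model."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    family: str
    sigma2: float | None = None
    tau2: float | None = None
    llf: float | None = None
    p_adjusted: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def classify_samples(
    detection: pd.DataFrame,
    calls: pd.Series,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Join encoder status, converter status, and participant metadata per sample.

    ``detection`` must already be restricted to the sterol-dehydrogenase
    clusters; a sample is an encoder when any of them is detected. Samples
    lacking metadata are excluded with a warning.
    """
    samples = detection.columns.intersection(calls.index)
    encoder = detection[samples].astype(bool).any(axis=0)
    missing = [s for s in samples if s not in metadata.index]
    if missing:
        warnings.warn(
            f"excluding {len(missing)} sample(s) without metadata: {missing[:5]}",
            stacklevel=2,
        )
    kept = [s for s in samples if s in metadata.index]
    out = metadata.loc[kept].copy()
    out.insert(0, "encoder", encoder.loc[kept])
    out.insert(1, "converter", calls.loc[kept].astype(bool))
    return out


def odds_ratio(
    table: ContingencyTable,
    method: str = "woolf",
    alpha: float = 0.05,
) -> OddsRatioResult:
    """Odds ratio with confidence interval for a 2x2 table.

    ``woolf`` (default) is the log-normal interval
    exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); any zero cell triggers
    the Haldane-Anscombe +0.5 correction to all four cells, flagged in the
    result. ``fisher`` gives the conditional (hypergeometric) MLE and exact
    interval. An empty table margin leaves the OR undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("odds ratio undefined: an entire row or column of the 2x2 is zero")
    if method == "fisher":
        res = st.contingency.odds_ratio([[a, b], [c, d]])
        ci = res.confidence_interval(confidence_level=1 - alpha)
        return OddsRatioResult(res.statistic, ci.low, ci.high, "fisher", False)
    if method != "woolf":
        raise ValueError(f"unknown method {method!r}")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = st.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=float(np.exp(np.log(or_) - half)),
        ci_high=float(np.exp(np.log(or_) + half)),
        method="woolf",
        correction_applied=corrected,
    )


def transform_metabolite(values, pseudo: float = 1e-5) -> np.ndarray:
    """log10 transform (zeros replaced by a pseudo-count) followed by z-scoring.

    The z-score uses the sample standard deviation (n - 1). A constant vector
    has no scale and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    if (x < 0).any():
        raise ValueError("metabolite abundances must be non-negative")
    logged = np.log10(np.where(x == 0, pseudo, x))
    sd = logged.std(ddof=1)
    if sd == 0:
        raise ValueError("constant metabolite vector: standard deviation is zero")
    return (logged - logged.mean()) / sd


def build_design(
    data: pd.DataFrame,
    predictors: list[str],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Design matrix with dummy-coded categoricals (first level alphabetically
    as reference) and booleans as 0/1."""
    cols = []
    for name in predictors:
        col = data[name]
        if col.dtype == bool:
            cols.append(col.astype(float).rename(name))
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols.append((col.astype(str) == level).astype(float).rename(f"{name}[{level}]"))
        else:
            cols.append(col.astype(float).rename(name))
    X = pd.concat(cols, axis=1)
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full column rank
        culprits = [
            col
            for col in X.columns
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")


def fit_linear(y, X: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with Wald tests; the design must be full rank."""
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    _check_full_rank(X)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        n=len(y),
        family="linear",
        sigma2=float(res.scale),
        llf=float(res.llf),
    )


def fit_logistic(y, X: pd.DataFrame, maxiter: int = 100) -> RegressionResult:
    """Logistic regression by maximum likelihood (IRLS / Newton).

    Raises :class:`SeparationError` on complete separation, detected either by
    statsmodels or by diverging coefficients.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    _check_full_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=maxiter)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError("complete separation: logistic MLE does not exist") from exc
    if np.abs(res.params).max() > 50:
        raise SeparationError("diverging coefficients suggest (quasi-)separation")
    return RegressionResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        n=len(y),
        family="logistic",
        llf=float(res.llf),
    )


def fit_random_intercept(y, X: pd.DataFrame, groups) -> RegressionResult:
    """Linear model with a per-participant random intercept, fitted by ML.

    y = X beta + u_group + eps with u ~ N(0, tau^2), eps ~ N(0, sigma^2);
    used for cohorts with repeated stool samples per participant. Fixed-effect
    tests are normal-approximation Wald tests. Requires at least one group
    with two or more observations, otherwise tau^2 is unidentifiable and OLS
    (``fit_linear``) should be used instead.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).all():
        raise ValueError(
            "all groups are singletons: the random intercept is unidentifiable; "
            "use fit_linear instead"
        )
    _check_full_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=False)
    # tau^2 = 0 lies in the feasible set; if the pure-OLS Gaussian ML fit is
    # at least as likely, the MLE sits on that boundary and the optimizer's
    # small positive tau^2 is numerical slack.
    ols = sm.OLS(y, X).fit()
    if ols.llf >= res.llf - 1e-8:
        return RegressionResult(
            params=ols.params,
            bse=ols.bse,
            tvalues=ols.tvalues,
            pvalues=ols.pvalues,
            n=len(y),
            family="linear-mixed",
            sigma2=float(ols.ssr / len(y)),
            tau2=0.0,
            llf=float(ols.llf),
        )
    fe = X.columns
    return RegressionResult(
        params=res.params[fe],
        bse=res.bse[fe],
        tvalues=res.tvalues[fe],
        pvalues=res.pvalues[fe],
        n=len(y),
        family="linear-mixed",
        sigma2=float(res.scale),
        tau2=float(np.asarray(res.cov_re)[0, 0]),
        llf=float(res.llf),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
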