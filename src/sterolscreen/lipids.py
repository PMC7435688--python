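"""Serum-lipid associations and cross-study random-effects meta-analysis.

Per-study effects of encoder status on serum lipids (total cholesterol, HDL-C,
LDL-C in mmol/L) come from covariate-adjusted linear models; studies are then
pooled with an inverse-variance DerSimonian-Laird random-effects model,
reporting the between-study variance tau^2, Cochran's Q and the I^2
heterogeneity percentage. Also provides the Friedewald LDL calculation and
the SD-unit -> mmol/L conversion used to compare against GWAS effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .assoc import build_design, fit_linear

__all__ = [
    "StudyEffect",
    "MetaResult",
    "friedewald_ldl",
    "study_effect",
    "meta_random_effects",
    "convert_sd_to_mmol",
]


@dataclass(frozen=True)
class StudyEffect:
    """Encoder-vs-non-encoder difference for one lipid in one study."""

    study: str
    lipid: str
    estimate: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    ci_low: float
    ci_high: float
    tau_squared: float
    q: float
    i_squared: float
    k: int


def friedewald_ldl(tc, hdl, tg, divisor: float = 2.2, tg_limit: float = 4.5):
    """Friedewald LDL-C: TC - HDL - TG/2.2 (all mmol/L).

    The equation is invalid at high triglycerides; TG above ``tg_limit``
    (4.5 mmol/L) raises. A negative result is returned as-is with a warning
    rather than clipped. For mg/dL inputs use ``divisor=5`` and an
    appropriately scaled ``tg_limit``.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if (tc < 0).any() or (hdl < 0).any() or (tg < 0).any():
        raise ValueError("lipid concentrations must be non-negative")
    if (tg > tg_limit).any():
        raise ValueError(f"Friedewald equation invalid for TG > {tg_limit} mmol/L")
    ldl = tc - hdl - tg / divisor
    if (ldl < 0).any():
        warnings.warn("Friedewald LDL is negative for some samples", stacklevel=2)
    if ldl.ndim == 0:
        return float(ldl)
    return ldl


def study_effect(
    data: pd.DataFrame,
    lipid: str,
    study: str,
    covariates: list[str] = ("age", "sex", "antibiotics", "statin"),
) -> StudyEffect:
    """Encoder coefficient (mmol/L) from a covariate-adjusted linear model.

    ``data`` needs a boolean ``encoder`` column, the lipid outcome column, and
    the covariate columns (default: age, sex, antibiotic usage, statin usage).
    """
    enc = data["encoder"].astype(bool)
    if enc.all() or (~enc).all():
        raise ValueError("need both encoders and non-encoders to estimate an effect")
    X = build_design(data, ["encoder", *covariates])
    res = fit_linear(data[lipid].to_numpy(), X)
    return StudyEffect(
        study=study,
        lipid=lipid,
        estimate=float(res.params["encoder"]),
        se=float(res.bse["encoder"]),
        n=res.n,
    )


def meta_random_effects(effects: list[StudyEffect], alpha: float = 0.05) -> MetaResult:
    """Inverse-variance random-effects pooling (DerSimonian-Laird).

    Fixed weights w_i = 1/se_i^2 give the fixed-effect mean and Cochran's
    Q = sum w_i (theta_i - theta_FE)^2; the moment estimator
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) feeds random
    weights w*_i = 1/(se_i^2 + tau^2). I^2 = max(0, (Q - (k-1))/Q) * 100.
    With a single study the pooled estimate and CI reduce to that study's.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("meta-analysis needs at least one study")
    theta = np.array([e.estimate for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / se**2
    theta_fe = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    if k == 1:
        tau2 = 0.0
        i2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    z = st.norm.ppf(1 - alpha / 2)
    half = z / np.sqrt(np.sum(w_star))
    return MetaResult(
        pooled=pooled,
        ci_low=pooled - half,
        ci_high=pooled + half,
        tau_squared=float(tau2),
        q=q,
        i_squared=float(i2),
        k=k,
    )


def forest_table(effects: list[StudyEffect], meta: MetaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-study rows (estimate, CI, random-effects weight %) plus the pooled row."""
    z = st.norm.ppf(1 - alpha / 2)
    w_star = np.array([1.0 / (e.se**2 + meta.tau_squared) for e in effects])
    weights = 100 * w_star / w_star.sum()
    rows = [
        {
            "study": e.study,
            "estimate": e.estimate,
            "ci_low": e.estimate - z * e.se,
            "ci_high": e.estimate + z * e.se,
            "weight_pct": wt,
        }
        for e, wt in zip(effects, weights)
    ]
    rows.append(
        {
            "study": "pooled (RE)",
            "estimate": meta.pooled,
            "ci_low": meta.ci_low,
            "ci_high": meta.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def convert_sd_to_mmol(beta_sd: float, cohort_sd: float) -> float:
    """Convert a GWAS effect in SD units to mmol/L using the cohort lipid SD.

    Reported to three decimal places, matching how such per-allele effects are
    conventionally printed.
    """
    if cohort_sd <= 0:
        raise ValueError("cohort standard deviation must be positive")
    return round(beta_sd * cohort_sd, 3)
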