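"""Probit dose-mortality analysis.

Fits the classical probit model — binomial mortality with a probit link on
log10 concentration — by maximum likelihood, and reports lethal
concentrations LC_p with 95% confidence limits (Fieller's theorem on the
log10 scale, with Finney's heterogeneity-factor inflation when the Pearson
χ² exceeds its degrees of freedom), plus resistance ratios between strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DoseResponseData", "ProbitFit", "LCEstimate",
    "fit_probit", "lc_estimate", "lc_from_params",
    "resistance_ratio", "abbott_correction",
]


class ProbitError(ValueError):
    """Raised when a dose-response dataset cannot identify the model."""


@dataclass
class DoseResponseData:
    """Dose-mortality records: concentration (mg/L), treated and dead counts.

    A record with concentration 0 is the untreated control. Counts may be
    fractional after Abbott's correction.
    """

    table: pd.DataFrame  # columns: concentration, n_treated, n_dead [, replicate]

    def __post_init__(self) -> None:
        t = self.table
        required = {"concentration", "n_treated", "n_dead"}
        if not required.issubset(t.columns):
            raise ValueError(f"need columns {sorted(required)}")
        if (t["concentration"] < 0).any():
            raise ValueError("negative concentration")
        if ((t["n_dead"] < 0) | (t["n_dead"] > t["n_treated"])).any():
            raise ValueError("n_dead must lie in [0, n_treated]")

    @classmethod
    def from_records(cls, records) -> "DoseResponseData":
        return cls(pd.DataFrame(records,
                                columns=["concentration", "n_treated", "n_dead"]))

    @classmethod
    def read_csv(cls, path) -> "DoseResponseData":
        return cls(pd.read_csv(path, comment="#"))

    def grouped(self) -> pd.DataFrame:
        """Aggregate replicates by concentration (positive doses only)."""
        t = self.table[self.table["concentration"] > 0]
        return (t.groupby("concentration", as_index=False)
                [["n_treated", "n_dead"]].sum()
                .sort_values("concentration", ignore_index=True))

    def control(self) -> pd.Series | None:
        ctrl = self.table[self.table["concentration"] == 0]
        if ctrl.empty:
            return None
        return ctrl[["n_treated", "n_dead"]].sum()


@dataclass
class LCEstimate:
    p: float          # mortality percentile, in (0, 100)
    value: float      # concentration, mg/L
    lower: float      # 95% confidence limits (NaN when Fieller's g >= 1)
    upper: float


@dataclass
class ProbitFit:
    """MLE of probit(π) = intercept + slope·log10(dose)."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov: np.ndarray           # 2x2 covariance of (intercept, slope)
    chi2: float               # Pearson goodness-of-fit
    df: int                   # dose groups - 2
    heterogeneity: float      # max(1, chi2/df), Finney's variance inflation
    n_groups: int = 0
    lc: dict[float, LCEstimate] = field(default_factory=dict)

    @classmethod
    def from_slope_lc50(cls, slope: float, lc50: float,
                        se_slope: float = float("nan")) -> "ProbitFit":
        """Reconstruct a point fit from published slope/LC50 summaries
        (no covariance information: confidence limits unavailable)."""
        intercept = -slope * np.log10(lc50)
        return cls(intercept=float(intercept), slope=float(slope),
                   se_intercept=float("nan"), se_slope=se_slope,
                   cov=np.full((2, 2), np.nan), chi2=float("nan"),
                   df=0, heterogeneity=1.0)


def fit_probit(data: DoseResponseData) -> ProbitFit:
    """Fit the probit dose-mortality model by maximum likelihood.

    Standard errors come from the observed information matrix; the Pearson
    χ² on the dose groups (df = groups − 2) measures goodness of fit, and
    its ratio to df — when above 1 — inflates all variances downstream.
    """
    groups = data.grouped()
    if len(groups) < 2:
        raise ProbitError("need at least 2 distinct positive concentrations")
    prop = groups["n_dead"] / groups["n_treated"]
    if ((prop == 0) | (prop == 1)).all():
        raise ProbitError(
            "all dose groups fully dead or fully alive: slope not identifiable")
    x = sm.add_constant(np.log10(groups["concentration"].to_numpy()))
    endog = np.column_stack([groups["n_dead"], groups["n_treated"] - groups["n_dead"]])
    model = sm.GLM(endog, x, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit()
    cov = np.asarray(res.cov_params())
    df = len(groups) - 2
    chi2 = float(res.pearson_chi2)
    h = max(1.0, chi2 / df) if df > 0 else 1.0
    fit = ProbitFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        se_intercept=float(np.sqrt(cov[0, 0])), se_slope=float(np.sqrt(cov[1, 1])),
        cov=cov, chi2=chi2, df=df, heterogeneity=h, n_groups=len(groups))
    return fit


def lc_from_params(slope: float, lc50: float, p: float) -> float:
    """LC_p implied by a slope/LC50 pair: LC_p = LC50 · 10^(Φ⁻¹(p/100)/slope).

    This is the quantile relation of the probit line on the log10 scale; it
    lets LC_p values be recomputed from published slope and LC50 summaries.
    """
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100) percent")
    if slope <= 0:
        raise ValueError("slope must be positive for a finite LC")
    return float(lc50 * 10.0 ** (stats.norm.ppf(p / 100.0) / slope))


def lc_estimate(fit: ProbitFit, p: float, method: str = "fieller") -> LCEstimate:
    """LC_p point estimate with 95% confidence limits.

    The point estimate is 10^((Φ⁻¹(p/100) − intercept)/slope). Limits are
    computed on the log10 scale by Fieller's theorem (default) or the delta
    method, both inflated by the heterogeneity factor; with over-dispersion
    (h > 1) the normal critical value is replaced by Student's t on the
    goodness-of-fit df, following the classical probit convention.
    """
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100) percent")
    if fit.slope <= 0:
        raise ValueError("non-positive slope: LC_p undefined")
    y0 = stats.norm.ppf(p / 100.0)
    rho = (y0 - fit.intercept) / fit.slope  # log10 LC_p
    point = 10.0 ** rho
    if not np.all(np.isfinite(fit.cov)):
        est = LCEstimate(p=p, value=float(point),
                         lower=float("nan"), upper=float("nan"))
        fit.lc[p] = est
        return est
    h = fit.heterogeneity
    crit = (stats.t.ppf(0.975, fit.df) if (h > 1 and fit.df > 0)
            else stats.norm.ppf(0.975))
    vaa, vab, vbb = fit.cov[0, 0], fit.cov[0, 1], fit.cov[1, 1]
    a, b = fit.intercept, fit.slope
    if method == "fieller":
        T = crit ** 2 * h
        # roots of (a + b·rho − y0)² = T·(vaa + 2·rho·vab + rho²·vbb)
        qa = b ** 2 - T * vbb
        qb = 2.0 * (b * (a - y0) - T * vab)
        qc = (a - y0) ** 2 - T * vaa
        disc = qb ** 2 - 4.0 * qa * qc
        if qa <= 0 or disc < 0:  # g >= 1: the fiducial interval is unbounded
            lo, hi = float("nan"), float("nan")
        else:
            r1 = (-qb - np.sqrt(disc)) / (2.0 * qa)
            r2 = (-qb + np.sqrt(disc)) / (2.0 * qa)
            lo, hi = 10.0 ** r1, 10.0 ** r2
    elif method == "delta":
        var_rho = h * (vaa + 2.0 * rho * vab + rho ** 2 * vbb) / b ** 2
        half = crit * np.sqrt(var_rho)
        lo, hi = 10.0 ** (rho - half), 10.0 ** (rho + half)
    else:
        raise ValueError(f"unknown CL method {method!r}")
    est = LCEstimate(p=p, value=float(point), lower=float(lo), upper=float(hi))
    fit.lc[p] = est
    return est


@dataclass
class ResistanceRatio:
    value: float
    reference: str = "susceptible"


def resistance_ratio(lc50_test: float, lc50_reference: float,
                     reference: str = "susceptible") -> ResistanceRatio:
    """LC50 of the test strain over the LC50 of the reference strain."""
    if lc50_reference <= 0:
        raise ValueError("reference LC50 must be positive")
    if lc50_test <= 0:
        raise ValueError("test LC50 must be positive")
    return ResistanceRatio(value=lc50_test / lc50_reference, reference=reference)


def abbott_correction(data: DoseResponseData) -> DoseResponseData:
    """Rescale treated mortality for control mortality c: p' = (p − c)/(1 − c),
    clamped at 0, with dead counts re-expressed as effective (possibly
    fractional) counts. Identity when control mortality is zero."""
    ctrl = data.control()
    if ctrl is None:
        raise ValueError("no control record (concentration 0) present")
    c = ctrl["n_dead"] / ctrl["n_treated"]
    if c >= 1.0:
        raise ValueError("control mortality is 100%: correction undefined")
    t = data.table[data.table["concentration"] > 0].copy()
    p = t["n_dead"] / t["n_treated"]
    p_adj = np.clip((p - c) / (1.0 - c), 0.0, 1.0)
    t["n_dead"] = p_adj * t["n_treated"]
    return DoseResponseData(t.reset_index(drop=True))
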