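"""Statistical analysis chain for adaptation-time effects.

Covers, in pipeline order: per-series rank scaling of nEUD values; the trend
ANCOVA that classifies series as time-sensitive or time-insensitive;
fixed-effects repeated-measures slope estimates (inter- vs intrafraction);
distribution-free percentile estimates with order-statistic confidence
intervals (the adaptation-time terciles); Kruskal-Wallis distribution
comparisons; the bivariate logistic model P(nEUD < threshold | time, margin);
and the delta-method margin-compensation rate derived from that fit, i.e.
how many extra millimetres of PTV margin offset an extra minute of
adaptation time.

All tests are two-sided.  No multiple-testing correction is applied; the
analysis is reported test-by-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TrendResult",
    "LogisticFit",
    "PercentileEstimate",
    "rank_scale",
    "trend_ancova",
    "repeated_trend",
    "percentile_ci",
    "compare_distributions",
    "fit_logistic_time_margin",
    "margin_compensation",
    "max_safe_time",
    "correlation_spearman",
]


@dataclass
class TrendResult:
    """Per-series and pooled time trends of rank-scaled nEUD values."""

    per_series_slope: Dict[str, Tuple[float, float]]  # series -> (slope, se)
    overall_slope: float
    overall_slope_se: float
    p_overall: float
    p_heterogeneity: float
    sensitivity_labels: Dict[str, str]

    def series_of(self, label: str) -> list:
        return sorted(k for k, v in self.sensitivity_labels.items() if v == label)


@dataclass
class LogisticFit:
    """Bivariate logistic fit: logit P(below) = b0 + b_t * time + b_m * margin."""

    beta: np.ndarray  # (intercept, per-min, per-mm)
    covariance: np.ndarray  # 3x3
    n_obs: int
    converged: bool
    llf: float = np.nan

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.beta.shape != (3,) or self.covariance.shape != (3, 3):
            raise ValueError("expected 3 coefficients and a 3x3 covariance")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8, equal_nan=True):
            raise ValueError("covariance must be symmetric")
        if self.converged and np.linalg.eigvalsh(
            (self.covariance + self.covariance.T) / 2
        ).min() < -1e-8:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def beta_time(self) -> float:
        return float(self.beta[1])

    @property
    def beta_margin(self) -> float:
        return float(self.beta[2])

    def predict(self, time_min: float, margin_mm: float) -> float:
        return float(expit(self.beta @ np.array([1.0, time_min, margin_mm])))


@dataclass
class PercentileEstimate:
    p: float  # percentile in (0, 100)
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    widened: bool = False  # CI clipped to the sample range at extreme p / small n

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("percentile CI must bracket the estimate")


# ---------------------------------------------------------------------------
# rank transform and trend models


def rank_scale(values: Sequence[float], by_group: Sequence) -> np.ndarray:
    """Within-group ranks (average ties) scaled linearly onto [0, 1].

    The rank transform stabilises the residual variance of nEUD values across
    adaptation times; the minimum of a group maps to 0 and its maximum to 1.
    A constant group carries no ordering information and maps to all 0.5
    (with a warning).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(by_group)
    if values.shape != groups.shape:
        raise ValueError("values and grouping must have equal length")
    out = np.empty_like(values)
    for g in np.unique(groups):
        sel = groups == g
        v = values[sel]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if np.ptp(v) == 0:
            warnings.warn(f"group {g!r} is constant; scaled ranks set to 0.5", stacklevel=2)
            out[sel] = 0.5
            continue
        ranks = sps.rankdata(v, method="average")
        out[sel] = (ranks - 1.0) / (v.size - 1.0)
    return out


def trend_ancova(
    scaled_ranks: Sequence[float],
    times: Sequence[float],
    series_ids: Sequence,
    classify_by: str = "common_slope",
) -> TrendResult:
    """Analysis of covariance of rank-scaled nEUD on adaptation time.

    Fits (i) a no-interaction model with series main effects and a common
    time slope (the overall slope and its test) and (ii) the full model with
    series x time interaction (per-series slopes and the heterogeneity
    F-test).  Series with slopes below the overall slope are labelled
    time-sensitive: their target dose degrades faster than the cohort
    average.

    ``classify_by`` selects the reference slope: ``"common_slope"`` (default)
    uses the no-interaction estimate, ``"mean_of_slopes"`` the unweighted
    mean of per-series slopes.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(scaled_ranks, dtype=float),
            "t": np.asarray(times, dtype=float),
            "series": [str(s) for s in series_ids],
        }
    )
    series = sorted(df["series"].unique())
    if len(series) < 2:
        raise ValueError("trend ANCOVA requires at least 2 series")
    counts = df.groupby("series").size()
    if (counts < 3).any():
        raise ValueError(
            f"series with fewer than 3 fractions: {list(counts[counts < 3].index)}"
        )
    for sid, sub in df.groupby("series"):
        if np.ptp(sub["t"].to_numpy()) == 0:
            raise ValueError(f"series {sid!r} has constant adaptation times (rank-deficient)")

    m0 = smf.ols("y ~ C(series) + t", data=df).fit()
    m1 = smf.ols("y ~ C(series) * t", data=df).fit()

    overall = float(m0.params["t"])
    overall_se = float(m0.bse["t"])
    p_overall = float(m0.pvalues["t"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova emits df warnings on exact fits
        ftest = sm.stats.anova_lm(m0, m1)
    p_het = float(ftest["Pr(>F)"].iloc[1])
    if np.isnan(p_het):  # exact fit: zero residual in both models
        p_het = 1.0

    # per-series slopes from the interaction model: base slope + interaction
    base = series[0]
    cov = m1.cov_params()
    per_series: Dict[str, Tuple[float, float]] = {}
    for sid in series:
        if sid == base:
            slope = float(m1.params["t"])
            se = float(m1.bse["t"])
        else:
            term = f"C(series)[T.{sid}]:t"
            slope = float(m1.params["t"] + m1.params[term])
            var = cov.loc["t", "t"] + cov.loc[term, term] + 2 * cov.loc["t", term]
            se = float(np.sqrt(max(var, 0.0)))
        per_series[sid] = (slope, se)

    if classify_by == "common_slope":
        ref = overall
    elif classify_by == "mean_of_slopes":
        ref = float(np.mean([s for s, _ in per_series.values()]))
    else:
        raise ValueError(f"unknown classify_by {classify_by!r}")
    labels = {
        sid: ("time_sensitive" if slope < ref else "time_insensitive")
        for sid, (slope, _) in per_series.items()
    }
    return TrendResult(per_series, overall, overall_se, p_overall, p_het, labels)


def repeated_trend(
    neud_values: Sequence[float],
    times: Sequence[float],
    unit_ids: Sequence,
    mode: str = "interfraction",
) -> Tuple[float, float]:
    """Common time slope with per-unit fixed effects (slope, SE).

    ``mode="interfraction"`` treats the patient/series as the unit (one value
    per fraction at its clinical adaptation time); ``mode="intrafraction"``
    treats the dose fraction as the unit, with the model-time evaluations as
    repeated measures.  Residual variances are allowed to differ across time
    points: a first OLS pass estimates per-time-group variances, and the
    slope is re-fitted by weighted least squares when enough replication
    exists.  Intrafraction units with a single observation are dropped with
    a warning.
    """
    if mode not in ("interfraction", "intrafraction"):
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.DataFrame(
        {
            "y": np.asarray(neud_values, dtype=float),
            "t": np.asarray(times, dtype=float),
            "unit": [str(u) for u in unit_ids],
        }
    )
    if mode == "intrafraction":
        sizes = df.groupby("unit")["y"].size()
        singles = sizes[sizes < 2].index
        if len(singles):
            warnings.warn(
                f"dropping {len(singles)} unit(s) with a single observation",
                stacklevel=2,
            )
            df = df[~df["unit"].isin(singles)]
    if df["unit"].nunique() < 1 or len(df) < 3:
        raise ValueError("not enough data for a repeated-measures trend")

    ols = smf.ols("y ~ C(unit) + t", data=df).fit()

    # heteroscedastic refit: weight by inverse residual variance per time group
    df = df.assign(resid=ols.resid, tgroup=df["t"].round(3))
    gv = df.groupby("tgroup")["resid"].agg(["var", "size"])
    usable = gv.dropna()
    usable = usable[(usable["size"] >= 3) & (usable["var"] > 0)]
    if len(usable) >= 2 and usable["size"].sum() >= 0.8 * len(df):
        var_map = usable["var"]
        w = df["tgroup"].map(var_map)
        if w.notna().all():
            wls = smf.wls("y ~ C(unit) + t", data=df, weights=1.0 / w).fit()
            return float(wls.params["t"]), float(wls.bse["t"])
    return float(ols.params["t"]), float(ols.bse["t"])


# ---------------------------------------------------------------------------
# percentiles and distribution comparisons


def percentile_ci(
    values: Sequence[float], p: float, confidence: float = 0.95
) -> PercentileEstimate:
    """Percentile with a distribution-free order-statistic confidence interval.

    The point estimate interpolates order statistics linearly; the interval
    brackets the population percentile with at least the nominal coverage
    using binomial tail probabilities of the order-statistic ranks.  At
    extreme percentiles with small n the interval is widened to the sample
    range with a warning.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 values, got {n}")
    if not 0 < p < 100:
        raise ValueError("percentile must be in (0, 100)")
    q = p / 100.0
    est = float(np.percentile(x, p))  # linear order-statistic interpolation

    alpha = 1.0 - confidence
    # largest lower rank with P(X_(l) > xi_q) <= alpha/2, i.e. cdf(l-1) <= alpha/2
    cdf = sps.binom.cdf(np.arange(0, n + 1), n, q)
    lower_ok = np.nonzero(cdf[:-1] <= alpha / 2)[0]  # cdf index l-1 -> rank l
    upper_ok = np.nonzero(1.0 - cdf[:-1] <= alpha / 2)[0]
    widened = False
    if len(lower_ok):
        lo = x[lower_ok.max()]
    else:
        lo, widened = x[0], True
    if len(upper_ok):
        u_rank = upper_ok.min() + 1  # rank u with P(X_(u) < xi_q) <= alpha/2
        hi = x[min(u_rank, n) - 1] if u_rank <= n else x[-1]
        if u_rank > n:
            widened = True
    else:
        hi, widened = x[-1], True
    if widened:
        warnings.warn(
            f"order-statistic CI undefined at p={p} with n={n}; "
            "widened to the sample range",
            stacklevel=2,
        )
    lo, hi = min(lo, est), max(hi, est)
    return PercentileEstimate(p, est, float(lo), float(hi), confidence, widened)


def compare_distributions(groups: Sequence[Sequence[float]]):
    """Kruskal-Wallis test across two or more groups (two-sided).

    Returns ``(H, p)``.  With all values tied the statistic is undefined;
    (0.0, 1.0) is returned with a warning.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; comparison is uninformative", stacklevel=2)
        return 0.0, 1.0
    h, pval = sps.kruskal(*groups)
    return float(h), float(pval)


# ---------------------------------------------------------------------------
# logistic time-margin model


def fit_logistic_time_margin(
    records: Iterable[Tuple[float, float, int]]
) -> LogisticFit:
    """Maximum-likelihood logistic fit of P(nEUD below threshold | time, margin).

    ``records`` are (adaptation time min, PTV margin mm, below-threshold 0/1)
    triples.  Complete or quasi-complete separation is detected and reported
    via ``converged=False`` instead of returning runaway coefficients; a
    constant covariate raises (that coefficient is inestimable).
    """
    data = np.asarray([list(r) for r in records], dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("records must be (time, margin, indicator) triples")
    y = data[:, 2]
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("outcome indicator must be 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    for col, name in ((0, "time"), (1, "margin")):
        if np.ptp(data[:, col]) == 0:
            raise ValueError(f"{name} covariate is constant; coefficient inestimable")
    exog = sm.add_constant(data[:, :2])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            return LogisticFit(
                np.full(3, np.nan), np.eye(3) * np.nan, len(y), converged=False
            )
    beta = np.asarray(res.params, dtype=float)
    sep = (not res.mle_retvals.get("converged", False)) or np.abs(beta).max() > 50.0
    if sep:
        return LogisticFit(beta, np.eye(3) * np.nan, len(y), converged=False)
    return LogisticFit(
        beta, np.asarray(res.cov_params(), dtype=float), len(y), True, float(res.llf)
    )


def margin_compensation(
    fit: LogisticFit, delta_t: float = 5.0, tol: float = 1e-8
) -> Tuple[float, float]:
    """Extra PTV margin (mm) compensating a ``delta_t``-minute time extension.

    Along an iso-probability contour of the logistic model,
    delta_margin = -(b_t / b_m) * delta_t, positive when time degrades and
    margin protects coverage.  The standard error propagates the coefficient
    covariance through the ratio by the delta method:

        se = |delta_margin| * sqrt( (s_t/b_t)^2 + (s_m/b_m)^2
                                    - 2 cov(b_t, b_m)/(b_t b_m) )

    Returns ``(delta_margin, se)``; the SE is NaN when the fit carries no
    covariance.
    """
    bt, bm = fit.beta_time, fit.beta_margin
    if not np.isfinite(bm) or abs(bm) < tol:
        raise ValueError("margin coefficient is (near) zero: compensation unbounded")
    dm = -(bt / bm) * delta_t
    cov = fit.covariance
    if not np.isfinite(cov[1:, 1:]).all():
        return float(dm), float("nan")
    if bt == 0:
        return 0.0, float(abs(delta_t / bm) * np.sqrt(cov[1, 1]))
    rel_var = (
        cov[1, 1] / bt**2 + cov[2, 2] / bm**2 - 2.0 * cov[1, 2] / (bt * bm)
    )
    se = abs(dm) * np.sqrt(max(rel_var, 0.0))
    return float(dm), float(se)


def max_safe_time(
    fit: LogisticFit,
    margin: float,
    p_max: float = 0.05,
    confidence: float = 0.95,
    t_hi: float = 120.0,
    tol_min: float = 1e-3,
) -> float:
    """Longest adaptation time whose upper confidence limit of P(below) <= p_max.

    The upper ``confidence`` limit of the predicted probability at
    (t, margin) is the logistic transform of the linear predictor plus
    z * sqrt(x' Sigma x); the largest admissible t is found by bisection.
    Returns 0.0 (flagged via a warning) when the bound is already exceeded
    at t = 0.
    """
    if not np.isfinite(fit.covariance).all():
        raise ValueError("full coefficient covariance required")
    if not 0 < p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    z = sps.norm.ppf(0.5 + confidence / 2.0)

    def upper_p(t: float) -> float:
        x = np.array([1.0, t, margin])
        eta = float(fit.beta @ x)
        se = float(np.sqrt(max(x @ fit.covariance @ x, 0.0)))
        return expit(eta + z * se)

    if upper_p(0.0) > p_max:
        warnings.warn(
            f"upper confidence limit exceeds {p_max} already at t=0 "
            f"for margin {margin} mm",
            stacklevel=2,
        )
        return 0.0
    if upper_p(t_hi) <= p_max:
        return float(t_hi)
    lo, hi = 0.0, t_hi
    while hi - lo > tol_min:
        mid = (lo + hi) / 2.0
        if upper_p(mid) <= p_max:
            lo = mid
        else:
            hi = mid
    return float(lo)


def correlation_spearman(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """Spearman rank correlation with a Fisher-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable is constant")
    r, _ = sps.spearmanr(x, y)
    n = x.size
    if abs(r) >= 1.0:
        return float(r), (float(r), float(r))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + confidence / 2.0)
    return float(r), (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
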