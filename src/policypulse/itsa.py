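"""Interrupted time-series analysis (segmented regression) at known policy
dates.

The model for a daily outcome ``y_t`` with one interruption is::

    y_t = b0 + b1*time_t + b2*level_t + b3*trend_t [+ Fourier terms] + e_t

where ``time_t`` counts days since the series start, ``level_t`` is 0
before the intervention and 1 from the intervention date on, and
``trend_t`` counts days since the intervention (0 before).  ``b1`` is the
pre-intervention slope, ``b2`` the instantaneous level change, and ``b3``
the slope change after the intervention.  Optional Fourier pairs
sin/cos(2*pi*k*t/T) control seasonality.

Estimation is ordinary least squares.  Residual first-order autocorrelation
is diagnosed with the Durbin-Watson statistic; when it falls outside a
configurable band around 2, standard errors are replaced by Newey-West
(Bartlett-kernel HAC) standard errors.  P-values use the t distribution
with n - p degrees of freedom in either case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.stats.sandwich_covariance as sw
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .scoring import DailyAttitudeSeries

__all__ = [
    "ITSADesign",
    "ITSAFit",
    "PolicyEvent",
    "build_design",
    "counterfactual",
    "default_hac_lag",
    "durbin_watson",
    "fit_itsa",
    "newey_west_se",
    "plot_fit",
    "read_events_csv",
    "run_policy_panel",
]

#: DW band outside which HAC standard errors are used (values near 0 mean
#: positive, near 4 negative, first-order residual autocorrelation).
DW_LOWER_DEFAULT = 1.5
DW_UPPER_DEFAULT = 2.5


@dataclass(frozen=True)
class PolicyEvent:
    """A policy release: the intervention point of one segmented fit."""

    date: date
    name: str = ""
    policy_type: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", pd.Timestamp(self.date).date())


@dataclass(frozen=True)
class ITSADesign:
    """Design matrix for one segmented regression.

    Columns: const, time, level, trend, then sin_k/cos_k pairs for
    k = 1..fourier_k.  The intervention date itself counts as post
    (level = 1).
    """

    X: pd.DataFrame
    dates: pd.DatetimeIndex
    event_index: int
    fourier_k: int
    period: float

    @property
    def n_pre(self) -> int:
        return self.event_index

    @property
    def n_post(self) -> int:
        return len(self.dates) - self.event_index


def default_hac_lag(n: int) -> int:
    """Newey-West truncation lag rule of thumb: floor(4 * (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


def build_design(
    series: DailyAttitudeSeries,
    event: PolicyEvent,
    fourier_k: int = 0,
    period: float = 365.25,
) -> ITSADesign:
    """Build the segmented-regression design for ``series`` and ``event``.

    The event must fall strictly inside the series window (not the first or
    last day), and the series must have at least 4 + 2*fourier_k + 2
    observations so every coefficient is estimable with residual degrees of
    freedom left.
    """
    if fourier_k < 0:
        raise ValueError("fourier_k must be >= 0")
    n = len(series)
    min_n = 4 + 2 * fourier_k + 2
    if n < min_n:
        raise ValueError(f"series has {n} observations, need >= {min_n}")
    event_ts = pd.Timestamp(event.date)
    dates = series.dates
    if not (dates[0] < event_ts <= dates[-1]):
        raise ValueError(
            f"event {event.date} outside the open series window "
            f"({dates[0].date()}, {dates[-1].date()}]"
        )
    event_index = int(dates.searchsorted(event_ts))
    if event_index in (0, n):
        raise ValueError("event must not coincide with the first or last observation")

    t = np.arange(n, dtype=float)
    level = (t >= event_index).astype(float)
    trend = np.where(level > 0, t - event_index, 0.0)
    cols = {"const": np.ones(n), "time": t, "level": level, "trend": trend}
    for k in range(1, fourier_k + 1):
        cols[f"sin_{k}"] = np.sin(2.0 * np.pi * k * t / period)
        cols[f"cos_{k}"] = np.cos(2.0 * np.pi * k * t / period)
    X = pd.DataFrame(cols, index=dates)
    return ITSADesign(X=X, dates=dates, event_index=event_index, fourier_k=fourier_k, period=period)


@dataclass
class ITSAFit:
    """Coefficients, inference and diagnostics of one segmented regression."""

    params: pd.Series
    se: pd.Series
    t_stat: pd.Series
    p_value: pd.Series
    dw: float
    hac_used: bool
    hac_lag: int
    fourier_k: int
    n_pre: int
    n_post: int
    residuals: np.ndarray
    fitted: np.ndarray
    design: ITSADesign = field(repr=False)

    @property
    def beta0(self) -> float:
        return float(self.params["const"])

    @property
    def beta1(self) -> float:
        return float(self.params["time"])

    @property
    def beta2(self) -> float:
        return float(self.params["level"])

    @property
    def beta3(self) -> float:
        return float(self.params["trend"])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1 - alpha) confidence intervals using t(n - p)."""
        n, p = self.design.X.shape
        crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - p)
        return pd.DataFrame(
            {"lower": self.params - crit * self.se, "upper": self.params + crit * self.se}
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "t": self.t_stat, "p": self.p_value}
        )


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson statistic sum((e_t - e_{t-1})^2) / sum(e_t^2), in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    if not np.any(e):
        raise ValueError("all residuals are zero")
    return float(_sm_dw(e))


def newey_west_se(
    design: ITSADesign | pd.DataFrame | np.ndarray,
    residuals: Sequence[float],
    lag: int,
) -> np.ndarray:
    """Newey-West HAC standard errors with Bartlett weights 1 - l/(lag+1).

    ``lag = 0`` reduces to the heteroskedasticity-only (White/HC0) sandwich.
    """
    X = design.X.to_numpy() if isinstance(design, ITSADesign) else np.asarray(design, dtype=float)
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy()
    u = np.asarray(residuals, dtype=float)
    n = X.shape[0]
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag >= n:
        raise ValueError(f"lag {lag} must be smaller than the {n} observations")
    if u.shape[0] != n:
        raise ValueError("residual length does not match the design")
    meat = sw.S_hac_simple(X * u[:, None], nlags=lag)
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ meat @ bread
    return np.sqrt(np.diag(cov))


def fit_itsa(
    design: ITSADesign,
    y: Sequence[float] | DailyAttitudeSeries,
    dw_lower: float = DW_LOWER_DEFAULT,
    dw_upper: float = DW_UPPER_DEFAULT,
    hac_lag: int | None = None,
    force_hac: bool = False,
) -> ITSAFit:
    """OLS fit of the segmented regression with autocorrelation-aware SEs.

    When the Durbin-Watson statistic falls outside [dw_lower, dw_upper] (or
    ``force_hac`` is set), OLS standard errors are replaced by Newey-West
    HAC standard errors with ``hac_lag`` (default floor(4*(n/100)^(2/9))).
    """
    if isinstance(y, DailyAttitudeSeries):
        y = y.values
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} values, design has {n} rows")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # name the offending columns for the error message
        bad = []
        keep: list[str] = []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(col)
            else:
                bad.append(col)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    res = sm.OLS(y, X).fit()
    resid = np.asarray(res.resid, dtype=float)
    dw = durbin_watson(resid) if np.any(resid) else float("nan")
    lag = default_hac_lag(n) if hac_lag is None else int(hac_lag)
    hac_used = force_hac or (np.isfinite(dw) and not dw_lower <= dw <= dw_upper)
    if hac_used:
        se = pd.Series(newey_west_se(design, resid, lag), index=X.columns)
    else:
        se = pd.Series(np.asarray(res.bse, dtype=float), index=X.columns)
    params = pd.Series(np.asarray(res.params, dtype=float), index=X.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = params / se
    p_value = pd.Series(
        2.0 * stats.t.sf(np.abs(t_stat.to_numpy()), df=n - p), index=X.columns
    ).fillna(1.0)
    return ITSAFit(
        params=params,
        se=se,
        t_stat=t_stat,
        p_value=p_value,
        dw=dw,
        hac_used=bool(hac_used),
        hac_lag=lag,
        fourier_k=design.fourier_k,
        n_pre=design.n_pre,
        n_post=design.n_post,
        residuals=resid,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        design=design,
    )


def counterfactual(fit: ITSAFit, design: ITSADesign | None = None) -> np.ndarray:
    """Pre-intervention trend extrapolated with level and trend zeroed.

    Equals the fitted values exactly on all pre-intervention dates; the
    post-intervention gap (observed - counterfactual) is the realized
    intervention effect.
    """
    design = fit.design if design is None else design
    X0 = design.X.copy()
    X0["level"] = 0.0
    X0["trend"] = 0.0
    return X0.to_numpy() @ fit.params.to_numpy()


def run_policy_panel(
    series: DailyAttitudeSeries,
    events: Sequence[PolicyEvent],
    window_days: int | None = None,
    max_window_days: int = 90,
    min_side_obs: int = 7,
    fourier_k: int = 0,
    period: float = 365.25,
    dw_lower: float = DW_LOWER_DEFAULT,
    dw_upper: float = DW_UPPER_DEFAULT,
    hac_lag: int | None = None,
) -> tuple[pd.DataFrame, dict[str, ITSAFit]]:
    """Fit one single-interruption model per policy event.

    Each event is fitted on the sub-series [date - w, date + w] clipped to
    the study window, where ``w`` is ``window_days`` or, by default, the
    span to the neighboring events capped at ``max_window_days`` per side.
    Events with fewer than ``min_side_obs`` observations on either side are
    skipped with a warning.

    Returns a per-event report (node, date, beta1, p1, beta2, p2, beta3,
    p3, dw, hac_used) and the fitted models keyed by event name.
    """
    events = sorted(events, key=lambda e: e.date)
    rows = []
    fits: dict[str, ITSAFit] = {}
    start, end = series.dates[0], series.dates[-1]
    for i, event in enumerate(events):
        ts = pd.Timestamp(event.date)
        if window_days is None:
            left_gap = (ts - pd.Timestamp(events[i - 1].date)).days if i > 0 else max_window_days
            right_gap = (
                (pd.Timestamp(events[i + 1].date) - ts).days
                if i + 1 < len(events)
                else max_window_days
            )
            w_left = min(max(left_gap, 1), max_window_days)
            w_right = min(max(right_gap, 1), max_window_days)
        else:
            w_left = w_right = window_days
        lo = max(start, ts - timedelta(days=w_left))
        hi = min(end, ts + timedelta(days=w_right))
        mask = (series.dates >= lo) & (series.dates <= hi)
        sub_dates = series.dates[mask]
        event_pos = int(sub_dates.searchsorted(ts))
        n_sub = len(sub_dates)
        if event_pos < min_side_obs or n_sub - event_pos < min_side_obs:
            warnings.warn(
                f"event {event.name or event.date}: fewer than {min_side_obs} "
                "observations on one side of the intervention; skipped",
                stacklevel=2,
            )
            continue
        sub = DailyAttitudeSeries(
            dates=sub_dates,
            values=series.values[mask],
            n_comments=series.n_comments[mask],
            imputed=series.imputed[mask],
            norm_offset=series.norm_offset,
            norm_scale=series.norm_scale,
        )
        design = build_design(sub, event, fourier_k=fourier_k, period=period)
        fit = fit_itsa(design, sub.values, dw_lower=dw_lower, dw_upper=dw_upper, hac_lag=hac_lag)
        key = event.name or str(event.date)
        fits[key] = fit
        rows.append(
            {
                "node": key,
                "date": event.date,
                "policy_type": event.policy_type,
                "beta1": fit.beta1,
                "p1": float(fit.p_value["time"]),
                "beta2": fit.beta2,
                "p2": float(fit.p_value["level"]),
                "beta3": fit.beta3,
                "p3": float(fit.p_value["trend"]),
                "dw": fit.dw,
                "hac_used": fit.hac_used,
                "n_pre": fit.n_pre,
                "n_post": fit.n_post,
            }
        )
    return pd.DataFrame(rows), fits


def read_events_csv(path: str | Path) -> list[PolicyEvent]:
    """Read a policy event calendar CSV with columns date, name, policy_type."""
    df = pd.read_csv(path)
    return [
        PolicyEvent(
            date=pd.Timestamp(row["date"]).date(),
            name=str(row.get("name", "") or ""),
            policy_type=str(row.get("policy_type", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def plot_fit(
    fit: ITSAFit,
    y: Sequence[float] | DailyAttitudeSeries,
    path: str | Path | None = None,
    title: str = "",
):
    """Plot observed values, the segmented fit and the counterfactual."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(y, DailyAttitudeSeries):
        y = y.values
    dates = fit.design.dates
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(dates, y, ".", color="grey", alpha=0.6, label="observed")
    pre = slice(0, fit.design.event_index)
    post = slice(fit.design.event_index, None)
    ax.plot(dates[pre], fit.fitted[pre], "-", color="tab:blue", label="pre fit")
    ax.plot(dates[post], fit.fitted[post], "-", color="tab:red", label="post fit")
    cf = counterfactual(fit)
    ax.plot(dates[post], cf[post], "--", color="tab:blue", label="counterfactual")
    ax.axvline(dates[fit.design.event_index], color="k", lw=0.8)
    ax.set_ylabel("attitude value")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
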