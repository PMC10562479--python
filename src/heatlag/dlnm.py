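"""Distributed lag nonlinear model (DLNM) for daily death counts.

The model is a quasi-Poisson log-linear regression

    log E[ND_t] = intercept + crossbasis(x, lag)_t + trend(date)_t

fitted by iteratively reweighted least squares (IRLS).  The quasi-Poisson
dispersion is estimated from the Pearson chi-square and scales only the
coefficient covariance; point estimates coincide with Poisson maximum
likelihood.  The fitted exposure-lag surface is summarised as relative
risks centered at a reference exposure (the series median), with delta-method
confidence intervals on the linear-predictor scale, and reduced to a single
"lag days" integer by a contiguous-significance rule used to specify the
lagged features of the downstream learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import CrossBasis, build_crossbasis, trend_spline

__all__ = [
    "DLNM",
    "DLNMResults",
    "RRSurface",
    "LagDecision",
    "fit_dlnm",
    "predict_rr_surface",
    "specify_lag_days",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class RRSurface:
    """Centered relative-risk grid over (exposure, lag) with 95% CIs."""

    grid: pd.DataFrame            # columns: exposure, lag, rr, lo, hi
    cumulative: pd.DataFrame      # columns: exposure, rr, lo, hi
    reference: float

    def at(self, exposure: float, lag: int) -> pd.Series:
        g = self.grid
        row = g[(np.isclose(g["exposure"], exposure)) & (g["lag"] == lag)]
        if row.empty:
            raise KeyError(f"({exposure}, {lag}) not on the surface grid")
        return row.iloc[0]


@dataclass
class LagDecision:
    """Outcome of the lag-day specification rule."""

    lag_days: int
    significant: bool
    significant_lags: tuple[int, ...] = ()


@dataclass
class DLNMResults:
    """Fitted quasi-Poisson DLNM: coefficients, covariance and dispersion."""

    coef: np.ndarray
    cov: np.ndarray
    dispersion: float
    crossbasis: CrossBasis
    cb_slice: slice
    deviance: float
    n_iter: int
    fitted: np.ndarray = field(repr=False)
    design: np.ndarray = field(default=None, repr=False)
    n_obs: int = 0
    n_params: int = 0

    # -- relative-risk surface -----------------------------------------
    def rr_surface(
        self,
        exposure_grid: np.ndarray | None = None,
        reference: float | None = None,
        conf_level: float = 0.95,
    ) -> RRSurface:
        cb = self.crossbasis
        if exposure_grid is None:
            exposure_grid = np.quantile(cb.exposure, np.linspace(0.01, 0.99, 50))
        exposure_grid = np.unique(np.asarray(exposure_grid, dtype=float))
        if reference is None:
            reference = float(np.median(cb.exposure))
        z = stats.norm.ppf(0.5 + conf_level / 2.0)

        lags = np.arange(cb.max_lag + 1)
        lag_b = cb.lag_basis(lags)                           # (L+1, lag_df)
        dv = cb.var_basis(exposure_grid) - cb.var_basis(np.array([reference]))  # (G, var_df)
        theta = self.coef[self.cb_slice]
        sigma = self.cov[self.cb_slice, self.cb_slice]

        rows = []
        cum_rows = []
        for gi, x in enumerate(exposure_grid):
            # contrast for (x, l): c_{jk} = dv_j(x) * lag_b_k(l), flattened j-major
            contrasts = np.einsum("j,lk->ljk", dv[gi], lag_b).reshape(len(lags), -1)
            lp = contrasts @ theta
            se = np.sqrt(np.maximum(np.einsum("lc,cd,ld->l", contrasts, sigma, contrasts), 0.0))
            for l in lags:
                rows.append((x, int(l), np.exp(lp[l]),
                             np.exp(lp[l] - z * se[l]), np.exp(lp[l] + z * se[l])))
            c_cum = contrasts.sum(axis=0)
            lp_cum = float(c_cum @ theta)
            se_cum = float(np.sqrt(max(c_cum @ sigma @ c_cum, 0.0)))
            cum_rows.append((x, np.exp(lp_cum),
                             np.exp(lp_cum - z * se_cum), np.exp(lp_cum + z * se_cum)))

        grid = pd.DataFrame(rows, columns=["exposure", "lag", "rr", "lo", "hi"])
        cumulative = pd.DataFrame(cum_rows, columns=["exposure", "rr", "lo", "hi"])
        return RRSurface(grid=grid, cumulative=cumulative, reference=reference)

    def specify_lag_days(
        self, exposure_percentile: float = 95.0, conf_level: float = 0.95
    ) -> LagDecision:
        """Reduce the fitted lag-response curve to an integer lag-day count.

        At the upper-tail exposure (the ``exposure_percentile`` of the
        observed series) the pointwise CI of RR is examined at each integer
        lag 0..max_lag.  The rule returns the last lag of the contiguous
        significant run that starts at the first significant lag; if the run
        persists to the maximum lag the maximum is returned; if no lag is
        significant, 1 is returned with ``significant=False``.
        """
        cb = self.crossbasis
        x_hi = float(np.percentile(cb.exposure, exposure_percentile))
        surface = self.rr_surface(
            exposure_grid=np.array([x_hi]), conf_level=conf_level
        )
        g = surface.grid.sort_values("lag")
        sig = (g["lo"].to_numpy() > 1.0)
        sig_lags = tuple(int(l) for l in g["lag"].to_numpy()[sig])
        if not sig.any():
            return LagDecision(lag_days=1, significant=False)
        first = int(np.argmax(sig))
        last = first
        while last + 1 < len(sig) and sig[last + 1]:
            last += 1
        lag_days = cb.max_lag if last == cb.max_lag else max(last, 1)
        return LagDecision(lag_days=lag_days, significant=True,
                           significant_lags=sig_lags)


class DLNM:
    """Quasi-Poisson DLNM with a long-term trend spline.

    Parameters
    ----------
    max_lag : maximum lag in days (default 14).
    var_df, lag_df : degrees of freedom of the exposure and lag bases
        (default 2 each, giving a 4-column cross-basis).
    trend_df_per_year : trend-spline degrees of freedom per year of data.
    tol : relative deviance change declaring IRLS convergence.
    """

    def __init__(
        self,
        max_lag: int = 14,
        var_df: int = 2,
        lag_df: int = 2,
        trend_df_per_year: int = 2,
        max_iter: int = 100,
        tol: float = 1e-8,
    ):
        self.max_lag = max_lag
        self.var_df = var_df
        self.lag_df = lag_df
        self.trend_df_per_year = trend_df_per_year
        self.max_iter = max_iter
        self.tol = tol

    def fit(
        self,
        exposure: np.ndarray | pd.Series,
        deaths: np.ndarray | pd.Series,
        dates: pd.DatetimeIndex | pd.Series,
    ) -> DLNMResults:
        y = np.asarray(deaths, dtype=float)
        dates = pd.DatetimeIndex(pd.to_datetime(dates))
        if len(y) != len(dates):
            raise ValueError("deaths and dates must align")
        cb = build_crossbasis(
            exposure, dates, max_lag=self.max_lag, var_df=self.var_df, lag_df=self.lag_df
        )
        n_years = dates.year.nunique()
        trend_df = max(2, self.trend_df_per_year * n_years)
        day_index = (dates - dates[0]).days.to_numpy(dtype=float)
        trend = trend_spline(day_index, trend_df)
        # centred + orthonormalised trend block: spans the same functions but
        # keeps the design well conditioned at high trend df; the cross-basis
        # coefficients are invariant to this reparameterisation
        trend_q, _ = np.linalg.qr(trend - trend.mean(axis=0))

        design = np.column_stack([np.ones(len(y)), cb.matrix, trend_q])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient ({rank} < {design.shape[1]}); "
                "collinear basis columns"
            )
        coef, mu, deviance, n_iter, trace = _irls_poisson(
            design, y, max_iter=self.max_iter, tol=self.tol
        )
        resid_df = len(y) - design.shape[1]
        pearson = float(np.sum((y - mu) ** 2 / mu))
        dispersion = pearson / resid_df if resid_df > 0 else np.nan
        w = mu
        xtwx = design.T @ (design * w[:, None])
        cov = dispersion * np.linalg.inv(xtwx)
        cov = 0.5 * (cov + cov.T)
        return DLNMResults(
            coef=coef,
            cov=cov,
            dispersion=dispersion,
            crossbasis=cb,
            cb_slice=slice(1, 1 + cb.n_columns),
            deviance=deviance,
            n_iter=n_iter,
            fitted=mu,
            design=design,
            n_obs=len(y),
            n_params=design.shape[1],
        )


def _irls_poisson(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """Poisson log-link IRLS; returns (coef, mu, deviance, n_iter, trace)."""
    mu = np.clip(y, 0.5, None)
    eta = np.log(mu)
    dev_prev = np.inf
    trace: list[float] = []
    coef = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = np.clip(X @ coef, -30.0, 30.0)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        deviance = float(2.0 * np.sum(dev_terms))
        trace.append(deviance)
        if np.isfinite(dev_prev) and abs(deviance - dev_prev) <= tol * (abs(dev_prev) + 0.1):
            return coef, mu, deviance, it, trace
        dev_prev = deviance
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations", trace
    )


# -- thin functional wrappers ------------------------------------------


def fit_dlnm(
    exposure, deaths, dates, max_lag: int = 14, var_df: int = 2, lag_df: int = 2,
    trend_df_per_year: int = 2, **kwargs
) -> DLNMResults:
    model = DLNM(max_lag=max_lag, var_df=var_df, lag_df=lag_df,
                 trend_df_per_year=trend_df_per_year, **kwargs)
    return model.fit(exposure, deaths, dates)


def predict_rr_surface(
    fit: DLNMResults, exposure_grid=None, reference: float | None = None
) -> RRSurface:
    return fit.rr_surface(exposure_grid=exposure_grid, reference=reference)


def specify_lag_days(fit: DLNMResults, exposure_percentile: float = 95.0) -> LagDecision:
    return fit.specify_lag_days(exposure_percentile=exposure_percentile)
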