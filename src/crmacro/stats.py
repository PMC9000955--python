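"""Macroecological time-series statistics of relative-abundance data.

All statistics operate on the thresholded view of an
:class:`~crmacro.simulate.AbundanceTimeSeries`: a taxon is *present* at a
sampling time when its relative abundance exceeds the detection threshold
(default 1e-4), and below-detection abundances count as zero. The same code
path serves simulated and experimental tables.

Statistics
----------
richness              number of present taxa per sampling time (alpha)
taylor_fit            Taylor's law: OLS slope beta of log10 variance on
                      log10 mean abundance across taxa
abundance_changes     pooled log10 abundance changes Delta_l and their SD
fit_exponential_shape Laplace (two-sided exponential) MLE scale of the pool
restoring_slopes      per-taxon OLS slope of Delta_l on log10 abundance
residence_return_times durations of sustained presence/absence
fit_powerlaw_cutoff   discrete MLE of P(t) ~ t^nu * exp(-t/tau)
prevalence_and_rank   presence fractions, time-mean abundances, rank curve
pairwise_correlations Pearson correlations over shared-presence times
shuffle_times         random permutation of sampling times
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.stats import linregress

from .simulate import AbundanceTimeSeries

__all__ = [
    "SummaryStats",
    "richness",
    "taylor_fit",
    "abundance_changes",
    "fit_exponential_shape",
    "restoring_slopes",
    "residence_return_times",
    "fit_powerlaw_cutoff",
    "prevalence_and_rank",
    "pairwise_correlations",
    "shuffle_times",
    "summarize",
    "core_statistics",
]


@dataclass
class SummaryStats:
    """Bundle of the macroecological statistics of one time series."""

    alpha_t: np.ndarray
    alpha_bar: float
    beta: float
    taylor_intercept: float
    dl_pool: np.ndarray
    sigma_dl: float
    laplace_scale: float
    s_i: np.ndarray
    s_bar: float
    t_res: np.ndarray
    t_ret: np.ndarray
    nu_res: float
    tau_res: float
    nu_ret: float
    tau_ret: float
    p_i: np.ndarray
    mean_x: np.ndarray
    var_x: np.ndarray
    rank_abund: np.ndarray
    corr_pool: np.ndarray = field(default_factory=lambda: np.empty(0))

    def core(self) -> dict[str, float]:
        """The four statistics used for parameter fitting."""
        return {
            "alpha_bar": self.alpha_bar,
            "beta": self.beta,
            "sigma_dl": self.sigma_dl,
            "s_bar": self.s_bar,
        }

    def to_json_dict(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            out[key] = val.tolist() if isinstance(val, np.ndarray) else val
        return out


def _masked(series: AbundanceTimeSeries, mode: str = "zero") -> np.ndarray:
    """Thresholded abundances; ``mode='mask'`` uses NaN for absences."""
    if mode == "zero":
        return series.thresholded
    if mode == "mask":
        return np.where(series.present, series.x, np.nan)
    raise ValueError(f"unknown absence mode {mode!r}")


def richness(series: AbundanceTimeSeries) -> tuple[np.ndarray, float]:
    """Per-time richness alpha(T) and its mean."""
    alpha_t = series.present.sum(axis=0)
    return alpha_t, float(alpha_t.mean())


def taylor_fit(
    series: AbundanceTimeSeries, absence_mode: str = "zero"
) -> tuple[float, float]:
    """Taylor's-law exponent: OLS slope of log10 var on log10 mean.

    Taxa need nonzero time-mean and time-variance to enter the regression;
    absences count as zeros by default.
    """
    x = _masked(series, absence_mode)
    mean_x = np.nanmean(x, axis=1)
    var_x = np.nanvar(x, axis=1, ddof=0)
    ok = (mean_x > 0) & (var_x > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 taxa with nonzero mean and variance")
    fit = linregress(np.log10(mean_x[ok]), np.log10(var_x[ok]))
    return float(fit.slope), float(fit.intercept)


def abundance_changes(series: AbundanceTimeSeries) -> tuple[np.ndarray, float]:
    """Pooled log10 abundance changes and their sample SD.

    Delta_l(i, T) = log10(x_i(T+1) / x_i(T)), restricted to consecutive
    pairs where the taxon is present at both times.
    """
    x = series.x
    both = series.present[:, :-1] & series.present[:, 1:]
    if not both.any():
        raise ValueError("no consecutive presence pairs; empty Delta_l pool")
    dl = np.log10(x[:, 1:][both] / x[:, :-1][both])
    sd = float(np.std(dl, ddof=1)) if dl.size > 1 else 0.0
    return dl, sd


def fit_exponential_shape(dl_pool: np.ndarray) -> float:
    """Laplace MLE scale of the pooled Delta_l distribution.

    The maximum-likelihood scale of a two-sided exponential is the mean
    absolute deviation from the median.
    """
    dl = np.asarray(dl_pool, dtype=float)
    if dl.size == 0:
        raise ValueError("empty pool")
    return float(np.mean(np.abs(dl - np.median(dl))))


def restoring_slopes(
    series: AbundanceTimeSeries, min_points: int = 10
) -> tuple[np.ndarray, float]:
    """Per-taxon reversion slopes s_i and their mean.

    s_i is the OLS slope of Delta_l_i(T) on l_i(T) = log10 x_i(T) over the
    sampling times where the taxon is present at T and T+1. Taxa with fewer
    than ``min_points`` such pairs get NaN. The mean restoring slope tracks
    the environmental restoring force (-s_bar ~ k).
    """
    x = series.x
    present = series.present
    n = series.n_taxa
    s_i = np.full(n, np.nan)
    for i in range(n):
        both = present[i, :-1] & present[i, 1:]
        if both.sum() < min_points:
            continue
        l = np.log10(x[i, :-1][both])
        dl = np.log10(x[i, 1:][both]) - l
        if np.ptp(l) == 0:
            continue
        s_i[i] = linregress(l, dl).slope
    if np.all(np.isnan(s_i)):
        raise ValueError("no taxon has enough presence pairs for a slope")
    return s_i, float(np.nanmean(s_i))


def _completed_runs(present_row: np.ndarray, value: bool) -> list[int]:
    """Lengths of maximal runs of ``value`` bounded by transitions."""
    n = present_row.size
    runs = []
    start = None
    for t in range(n):
        if present_row[t] == value:
            if start is None:
                start = t
        else:
            if start is not None:
                if start > 0:  # left-bounded; right boundary is this transition
                    runs.append(t - start)
                start = None
    # a run touching the end of the window is censored and dropped
    return runs


def residence_return_times(
    series: AbundanceTimeSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Completed residence (presence) and return (absence) run lengths.

    Runs touching either end of the observation window are censored and
    excluded; only runs bounded by a transition on both sides are pooled.
    """
    present = series.present
    res, ret = [], []
    for i in range(series.n_taxa):
        res.extend(_completed_runs(present[i], True))
        ret.extend(_completed_runs(present[i], False))
    return np.asarray(res, dtype=int), np.asarray(ret, dtype=int)


def fit_powerlaw_cutoff(
    times: np.ndarray,
    t_max: int | None = None,
    min_intervals: int = 20,
    method: str = "mle",
) -> tuple[float, float]:
    """Fit P(t) proportional to t^nu * exp(-t/tau) over t = 1..t_max.

    ``method='mle'`` (default) maximizes the discrete likelihood, which is
    robust at small samples; ``'binned'`` does least squares of log counts
    on (log t, t). Returns the fitted (nu, tau); degenerate samples (all
    intervals equal) pin the fit at a boundary and return (nan, nan).
    """
    t = np.asarray(times, dtype=float)
    if t.size < min_intervals:
        raise ValueError(f"need >= {min_intervals} intervals, got {t.size}")
    if t.min() < 1:
        raise ValueError("interval lengths must be >= 1")
    if np.ptp(t) == 0:
        return float("nan"), float("nan")
    if method == "binned":
        lengths, counts = np.unique(t.astype(int), return_counts=True)
        if lengths.size < 3:
            return float("nan"), float("nan")
        # weight by sqrt(count): var(log c) ~ 1/c for Poisson bin counts
        w = np.sqrt(counts.astype(float))
        A = np.column_stack(
            [np.ones(lengths.size), np.log(lengths), -lengths.astype(float)]
        )
        coef, *_ = np.linalg.lstsq(
            A * w[:, None], np.log(counts.astype(float)) * w, rcond=None
        )
        inv_tau = max(coef[2], 1e-12)
        return float(coef[1]), float(1.0 / inv_tau)
    if method != "mle":
        raise ValueError(f"method must be 'mle' or 'binned', got {method!r}")
    if t_max is None:
        t_max = int(t.max()) * 3
    support = np.arange(1, t_max + 1, dtype=float)
    log_support = np.log(support)
    mean_log_t = float(np.mean(np.log(t)))
    mean_t = float(np.mean(t))

    def nll(theta):
        nu, log_tau = theta
        tau = np.exp(log_tau)
        logw = nu * log_support - support / tau
        logz = np.logaddexp.reduce(logw)
        return -(nu * mean_log_t - mean_t / tau - logz)

    best = None
    for nu0 in (-2.0, -1.0, 0.0):
        res = minimize(
            nll, x0=(nu0, np.log(mean_t)), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    nu, log_tau = best.x
    return float(nu), float(np.exp(log_tau))


def prevalence_and_rank(
    series: AbundanceTimeSeries,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Presence fraction, time-mean abundance (absences as 0), rank curve."""
    p_i = series.present.mean(axis=1)
    mean_x = series.thresholded.mean(axis=1)
    rank_abund = np.sort(mean_x)[::-1]
    return p_i, mean_x, rank_abund


def pairwise_correlations(
    series: AbundanceTimeSeries, min_shared: int = 10
) -> np.ndarray:
    """Pearson correlations of taxon pairs over shared-presence times.

    Pairs with fewer than ``min_shared`` co-presence times, or with zero
    variance over them, are skipped.
    """
    x = series.x
    present = series.present
    n = series.n_taxa
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            if both.sum() < min_shared:
                continue
            a, b = x[i, both], x[j, both]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return np.asarray(out)


def shuffle_times(
    series: AbundanceTimeSeries, rng: np.random.Generator
) -> AbundanceTimeSeries:
    """Permute sampling times uniformly at random (rows untouched).

    The permutation is recorded in ``meta['permutation']`` so a shuffle can
    be undone.
    """
    perm = rng.permutation(series.n_times)
    meta = dict(series.meta)
    meta["permutation"] = perm
    return AbundanceTimeSeries(
        x=series.x[:, perm], detect=series.detect,
        taxa_ids=list(series.taxa_ids), meta=meta,
    )


def summarize(
    series: AbundanceTimeSeries,
    *,
    min_points: int = 10,
    min_intervals: int = 20,
    with_correlations: bool = False,
) -> SummaryStats:
    """Compute the full statistics bundle for one time series.

    Residence/return power-law fits fall back to NaN when too few completed
    intervals exist; the four core fitting statistics are always computed.
    """
    alpha_t, alpha_bar = richness(series)
    beta, intercept = taylor_fit(series)
    dl, sigma_dl = abundance_changes(series)
    scale = fit_exponential_shape(dl)
    s_i, s_bar = restoring_slopes(series, min_points=min_points)
    t_res, t_ret = residence_return_times(series)
    nu_res = tau_res = nu_ret = tau_ret = float("nan")
    if t_res.size >= min_intervals:
        nu_res, tau_res = fit_powerlaw_cutoff(t_res, min_intervals=min_intervals)
    if t_ret.size >= min_intervals:
        nu_ret, tau_ret = fit_powerlaw_cutoff(t_ret, min_intervals=min_intervals)
    p_i, mean_x, rank_abund = prevalence_and_rank(series)
    x = series.thresholded
    corr = pairwise_correlations(series) if with_correlations else np.empty(0)
    return SummaryStats(
        alpha_t=alpha_t,
        alpha_bar=alpha_bar,
        beta=beta,
        taylor_intercept=intercept,
        dl_pool=dl,
        sigma_dl=sigma_dl,
        laplace_scale=scale,
        s_i=s_i,
        s_bar=s_bar,
        t_res=t_res,
        t_ret=t_ret,
        nu_res=nu_res,
        tau_res=tau_res,
        nu_ret=nu_ret,
        tau_ret=tau_ret,
        p_i=p_i,
        mean_x=np.mean(x, axis=1),
        var_x=np.var(x, axis=1, ddof=0),
        rank_abund=rank_abund,
        corr_pool=corr,
    )


def core_statistics(series: AbundanceTimeSeries, min_points: int = 10) -> dict:
    """The four fitting statistics: alpha_bar, beta, sigma_dl, s_bar."""
    _, alpha_bar = richness(series)
    beta, _ = taylor_fit(series)
    _, sigma_dl = abundance_changes(series)
    _, s_bar = restoring_slopes(series, min_points=min_points)
    return {
        "alpha_bar": alpha_bar,
        "beta": beta,
        "sigma_dl": sigma_dl,
        "s_bar": s_bar,
    }
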