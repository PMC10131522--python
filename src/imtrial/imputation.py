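"""EM imputation of missing diary days under a Gaussian AR(1) on log(count+1).

Diary counts are collected day by day, so missing days are imputed with a
time-series model before weekly totals are formed.  The model is a stationary
Gaussian AR(1) for the transformed series y_t = log(count_t + 1):

    y_t - mu = phi * (y_{t-1} - mu) + e_t,    e_t ~ Normal(0, sigma2_e),

with parameters pooled across all series of a phase and estimated by
expectation-maximisation.  The E-step runs an exact Kalman filter/smoother
(missing days simply skip the measurement update); the M-step updates mu in
closed form and profiles (phi, sigma2_e) with a 1-D maximisation, so each
iteration can only increase the observed-data log-likelihood.  Missing cells
are filled with their conditional expectation given the observed days,
back-transformed and rounded to the nearest non-negative integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .data import DailyDiarySeries, TrialDataset

_SIGMA2_FLOOR = 1e-10
_PHI_BOUND = 0.999


class UnfitError(ValueError):
    """The series collection carries no information to fit on."""


@dataclass
class AR1Params:
    """Stationary AR(1) parameters on the log(count+1) scale."""

    mu: float
    phi: float
    sigma2_e: float
    converged: bool = True
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be > 0")


def to_transformed(counts: np.ndarray) -> np.ndarray:
    return np.log(np.asarray(counts, dtype=float) + 1.0)


def from_transformed(y: np.ndarray) -> np.ndarray:
    counts = np.rint(np.expm1(y))
    return np.maximum(counts, 0.0)


def _pad_collection(series_list: list[np.ndarray]) -> np.ndarray:
    """Stack variable-length series into an (n, T_max) array padded with NaN."""
    tmax = max(len(s) for s in series_list)
    out = np.full((len(series_list), tmax), np.nan)
    for i, s in enumerate(series_list):
        out[i, : len(s)] = s
    return out


def _kalman_estep(y: np.ndarray, lengths: np.ndarray, mu: float, phi: float, sigma2: float):
    """Filter + RTS smoother over an (n, T) NaN-padded batch of series.

    Returns the observed-data log-likelihood and the smoothed moments of the
    state z_t = y_t - mu: means ``a_s``, variances ``P_s`` and lag-one
    covariances ``C`` (C[:, t] = Cov(z_t, z_{t-1} | data)).
    """
    n, tmax = y.shape
    obs = ~np.isnan(y)
    in_range = np.arange(tmax)[None, :] < lengths[:, None]

    a_pred = np.zeros((n, tmax))
    p_pred = np.zeros((n, tmax))
    a_filt = np.zeros((n, tmax))
    p_filt = np.zeros((n, tmax))

    var_stat = sigma2 / (1.0 - phi**2)
    loglik = 0.0
    a, p = np.zeros(n), np.full(n, var_stat)
    for t in range(tmax):
        if t > 0:
            a, p = phi * a, phi**2 * p + sigma2
        a_pred[:, t], p_pred[:, t] = a, p
        m = obs[:, t]
        if m.any():
            v = y[m, t] - mu - a[m]
            f = np.maximum(p[m], _SIGMA2_FLOOR)
            loglik += -0.5 * np.sum(np.log(2.0 * np.pi * f) + v**2 / f)
            a = a.copy()
            p = p.copy()
            a[m] = y[m, t] - mu
            p[m] = 0.0
        a_filt[:, t], p_filt[:, t] = a, p

    a_s = a_filt.copy()
    p_s = p_filt.copy()
    c = np.zeros((n, tmax))  # c[:, t] = Cov(z_t, z_{t-1} | data)
    last = lengths - 1
    for t in range(tmax - 2, -1, -1):
        active = t < last  # series still extending beyond t
        j = np.where(
            active, p_filt[:, t] * phi / np.maximum(p_pred[:, t + 1], _SIGMA2_FLOOR), 0.0
        )
        a_s[:, t] = np.where(active, a_filt[:, t] + j * (a_s[:, t + 1] - a_pred[:, t + 1]), a_s[:, t])
        p_s[:, t] = np.where(active, p_filt[:, t] + j**2 * (p_s[:, t + 1] - p_pred[:, t + 1]), p_s[:, t])
        c[:, t + 1] = np.where(active, j * p_s[:, t + 1], 0.0)

    a_s[~in_range] = 0.0
    p_s[~in_range] = 0.0
    c[~in_range] = 0.0
    return float(loglik), a_s, p_s, c


def fit_ar1_em(
    series_list: list[np.ndarray],
    max_iter: int = 200,
    tol: float = 1e-6,
) -> AR1Params:
    """Fit pooled AR(1) parameters by EM on a collection of transformed series.

    ``series_list`` holds 1-D float arrays on the log(count+1) scale, with NaN
    marking missing days.  Raises :class:`UnfitError` if any series is fully
    missing.  Non-convergence within ``max_iter`` sets ``converged=False``
    (with a warning) rather than raising.
    """
    series_list = [np.asarray(s, dtype=float).ravel() for s in series_list]
    if not series_list:
        raise UnfitError("empty series collection")
    for s in series_list:
        if np.all(np.isnan(s)):
            raise UnfitError("a series with all values missing cannot be fitted")

    y = _pad_collection(series_list)
    lengths = np.array([len(s) for s in series_list])
    obs_vals = y[~np.isnan(y)]

    mu = float(obs_vals.mean())
    phi = _lag1_autocorr(series_list, mu)
    sigma2 = max(float(obs_vals.var()) * (1.0 - phi**2), _SIGMA2_FLOOR)

    n1 = len(series_list)
    n2 = int((lengths - 1).sum())
    n_tot = n1 + n2

    logliks: list[float] = []
    converged = False
    for _ in range(max_iter):
        loglik, a_s, p_s, c = _kalman_estep(y, lengths, mu, phi, sigma2)
        logliks.append(loglik)
        if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
            converged = True
            break

        ey = a_s + mu  # E[y_t | data]; padded cells ignored via masks below
        t_idx = np.arange(y.shape[1])[None, :]
        first = t_idx == 0
        interior = (t_idx >= 1) & (t_idx < lengths[:, None])

        # CM step 1: mu given phi (stationary complete-data likelihood is quadratic in mu)
        ey1 = ey[:, 0]
        num = (1.0 - phi**2) * ey1.sum() + (1.0 - phi) * np.sum(
            (ey[:, 1:] - phi * ey[:, :-1]) * interior[:, 1:]
        )
        den = n1 * (1.0 - phi**2) + n2 * (1.0 - phi) ** 2
        mu = float(num / den)

        # CM step 2: profile (phi, sigma2) given the new mu
        d = ey - mu
        a_stat = float(np.sum((p_s[:, 0] + d[:, 0] ** 2) * first[:, 0]))
        w = interior[:, 1:]
        c0 = float(np.sum((p_s[:, 1:] + d[:, 1:] ** 2) * w))
        c1 = float(np.sum((c[:, 1:] + d[:, 1:] * d[:, :-1]) * w))
        c2 = float(np.sum((p_s[:, :-1] + d[:, :-1] ** 2) * w))

        def neg_q(ph: float) -> float:
            s2 = max(((1.0 - ph**2) * a_stat + c0 - 2.0 * ph * c1 + ph**2 * c2) / n_tot,
                     _SIGMA2_FLOOR)
            return -(0.5 * n1 * np.log(1.0 - ph**2) - 0.5 * n_tot * np.log(s2))

        res = minimize_scalar(neg_q, bounds=(-_PHI_BOUND, _PHI_BOUND), method="bounded")
        phi = float(res.x)
        sigma2 = max(
            ((1.0 - phi**2) * a_stat + c0 - 2.0 * phi * c1 + phi**2 * c2) / n_tot,
            _SIGMA2_FLOOR,
        )
    else:
        converged = False

    if not converged and max_iter > 1:
        warnings.warn("AR(1) EM did not converge within max_iter", stacklevel=2)
    return AR1Params(mu=mu, phi=phi, sigma2_e=max(sigma2, _SIGMA2_FLOOR),
                     converged=converged, loglik_path=logliks)


def _lag1_autocorr(series_list: list[np.ndarray], mu: float) -> float:
    num = den = 0.0
    for s in series_list:
        d = s - mu
        pair = ~np.isnan(d[1:]) & ~np.isnan(d[:-1])
        num += np.nansum(d[1:][pair] * d[:-1][pair])
        den += np.nansum(d[:-1][pair] ** 2) + np.nansum(d[1:][pair] ** 2)
    if den <= 0:
        return 0.0
    return float(np.clip(2.0 * num / den, -0.8, 0.8))


def conditional_mean_missing(values: np.ndarray, params: AR1Params) -> np.ndarray:
    """Conditional expectation of every cell given the observed cells.

    Observed cells are returned unchanged (the smoother reproduces them exactly
    because the diary measures the state without noise).
    """
    y = np.asarray(values, dtype=float)[None, :]
    _, a_s, _, _ = _kalman_estep(
        y, np.array([y.shape[1]]), params.mu, params.phi, params.sigma2_e
    )
    est = a_s[0] + params.mu
    out = y[0].copy()
    miss = np.isnan(out)
    out[miss] = est[miss]
    return out


def impute_series(series: DailyDiarySeries, params: AR1Params) -> DailyDiarySeries:
    """Fill missing diary days; observed days are never altered."""
    if series.n_observed == 0:
        raise UnfitError("cannot impute a series with no observed values")
    if series.is_complete:
        return series.copy()
    y = to_transformed(series.values)
    filled = conditional_mean_missing(y, params)
    counts = from_transformed(filled)
    out_vals = series.values.copy()
    miss = series.missing
    out_vals[miss] = counts[miss]
    imputed = series.imputed | miss
    return DailyDiarySeries(series.phase, out_vals, imputed)


def fit_phase(ds: TrialDataset, phase: str, **em_kwargs) -> AR1Params:
    """Pool all of one phase's diaries and fit the AR(1) by EM."""
    series = []
    for rec in ds:
        s = rec.baseline if phase == "baseline" else rec.week4
        if s is not None and s.n_observed > 0:
            series.append(to_transformed(s.values))
    if not series:
        raise UnfitError(f"no observed {phase} series to fit on")
    return fit_ar1_em(series, **em_kwargs)


def impute_dataset(
    ds: TrialDataset, params_by_phase: dict[str, AR1Params] | None = None, **em_kwargs
) -> TrialDataset:
    """Impute every incomplete diary, with per-phase pooled parameters.

    On complete data this is a no-op (a copy is still returned).
    """
    out = ds.copy()
    needs = {
        phase: any(
            (rec.baseline if phase == "baseline" else rec.week4) is not None
            and not (rec.baseline if phase == "baseline" else rec.week4).is_complete
            for rec in out
        )
        for phase in ("baseline", "week4")
    }
    if params_by_phase is None:
        params_by_phase = {}
        for phase, needed in needs.items():
            if needed:
                params_by_phase[phase] = fit_phase(out, phase, **em_kwargs)
    for rec in out:
        if not rec.baseline.is_complete:
            rec.baseline = impute_series(rec.baseline, params_by_phase["baseline"])
        if rec.week4 is not None and not rec.week4.is_complete and rec.week4.n_observed > 0:
            rec.week4 = impute_series(rec.week4, params_by_phase["week4"])
    return out


def weekly_total(series: DailyDiarySeries) -> int:
    """Primary-outcome weekly total: the sum of the 7 daily counts."""
    return series.total()
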