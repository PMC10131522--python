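"""Bayesian Poisson mixed model for week-4 diary counts.

The 7 week-4 daily counts of participant i are modelled as repeated Poisson
observations with a shared daily rate:

    y_ij ~ Poisson(lambda_i),   log lambda_i = b0 + b_base * x_i + b_treat * T_i + u_i,

with x_i the standardised baseline weekly total, T_i the treatment indicator
(immediate = 1, delayed = 0 reference) and u_i ~ Normal(0, sigma_u^2) a
participant random intercept.  Because the daily counts share one rate, the
weekly total s_i = sum_j y_ij is sufficient, and the random intercept can be
integrated out per participant with adaptive Gauss-Hermite quadrature.  That
leaves a 4-parameter marginal posterior over (b0, b_base, b_treat, sigma_u),
which is sampled exactly with an independence Metropolis-Hastings chain whose
proposal is a multivariate-t matched to the Laplace approximation (the
marginal posterior is close to Gaussian, so acceptance is high and the chains
are near-iid), or approximated by the Laplace fit alone for simulation-heavy
work.

A negative-binomial family switch is provided for the sensitivity suite: the
weekly total of 7 iid NB(mean lambda, shape alpha) days is NB(7 lambda, 7 alpha),
so the same marginalisation applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import multivariate_t, norm

from .config import Priors
from .data import DIARY_DAYS, TrialDataset

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(20)
_LOG_GH_WEIGHTS = np.log(_GH_WEIGHTS)


class DiagnosticError(RuntimeError):
    """Sampler diagnostics failed; carries the diagnostic report."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass
class ModelData:
    """Analysis-ready week-4 data: totals, standardised baseline, arm indicator."""

    totals: np.ndarray          # week-4 weekly totals s_i
    baseline_totals: np.ndarray
    treat: np.ndarray           # 1 = immediate, 0 = delayed (reference)
    day_counts: np.ndarray      # (n, 7) daily counts, for predictive checks
    participant_ids: list[str]
    x: np.ndarray = field(init=False)      # standardised baseline
    x_mean: float = field(init=False)
    x_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=float)
        self.baseline_totals = np.asarray(self.baseline_totals, dtype=float)
        self.treat = np.asarray(self.treat, dtype=float)
        if set(np.unique(self.treat)) - {0.0, 1.0}:
            raise ValueError("treatment indicator must be binary")
        if self.treat.min() == self.treat.max():
            raise ValueError("both arms must be present in the analysis data")
        self.x_mean = float(self.baseline_totals.mean())
        self.x_sd = float(self.baseline_totals.std(ddof=0)) or 1.0
        self.x = (self.baseline_totals - self.x_mean) / self.x_sd

    @property
    def n(self) -> int:
        return len(self.totals)


def build_model_data(ds: TrialDataset, min_observed_days: int = 4) -> ModelData:
    """Assemble complete (post-imputation) analysed participants into ModelData."""
    recs = ds.analysed(min_observed_days)
    if not recs:
        raise ValueError("no analysed participants")
    for rec in recs:
        if not rec.week4.is_complete or not rec.baseline.is_complete:
            raise ValueError(
                f"participant {rec.participant_id} has unimputed missing days; "
                "run imputation first"
            )
    return ModelData(
        totals=np.array([r.week4.total() for r in recs], dtype=float),
        baseline_totals=np.array([r.baseline.total() for r in recs], dtype=float),
        treat=np.array([1.0 if r.arm == "immediate" else 0.0 for r in recs]),
        day_counts=np.array([r.week4.values for r in recs]),
        participant_ids=[r.participant_id for r in recs],
    )


# ---------------------------------------------------------------------------
# marginal likelihood over the random intercept
# ---------------------------------------------------------------------------

def _log_kernel_poisson(s, j, eta_u):
    # log Poisson(s | j * exp(eta_u)) without the gammaln(s+1) data constant;
    # overflow at absurd proposals maps to -inf, which MH simply rejects
    with np.errstate(over="ignore", invalid="ignore"):
        out = s * (np.log(j) + eta_u) - j * np.exp(eta_u)
    return np.nan_to_num(out, nan=-np.inf, neginf=-np.inf)


def _log_kernel_negbin(s, j, eta_u, alpha):
    with np.errstate(over="ignore", invalid="ignore"):
        m = j * np.exp(eta_u)
        r = j * alpha
        out = (
            gammaln(s + r) - gammaln(r)
            + r * (np.log(r) - np.log(r + m))
            + s * (np.log(m) - np.log(r + m))
        )
    return np.nan_to_num(out, nan=-np.inf, neginf=-np.inf)


def marginal_loglik(
    theta: np.ndarray,
    data: ModelData,
    family: str = "poisson",
    alpha: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Log-likelihood with the random intercept integrated out, batched over theta.

    ``theta`` has shape (..., 4) = (b0, b_base, b_treat, sigma_u).  The
    integral over u uses adaptive Gauss-Hermite quadrature centred on the mode
    of each participant's integrand (Newton steps), which keeps 20 nodes
    accurate even for large counts.  Returns shape (...,).
    """
    theta = np.asarray(theta, dtype=float)
    squeeze = theta.ndim == 1
    theta = np.atleast_2d(theta)
    b0, bb, bt, su = theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3]
    s = data.totals            # (n,)
    j = float(DIARY_DAYS)
    eta = b0[..., None] + bb[..., None] * data.x + bt[..., None] * data.treat  # (..., n)
    eta = np.clip(eta, -30.0, 30.0)   # keeps exp() finite at absurd proposals

    out = np.empty(eta.shape[:-1])
    zero_su = su <= 1e-12
    if zero_su.any():
        ll = _log_kernel_poisson(s, j, eta) if family == "poisson" else None
        if family == "negbin":
            ll = _log_kernel_negbin(s, j, eta, alpha[..., None])
        out[zero_su] = ll[zero_su].sum(axis=-1)
    if (~zero_su).any():
        idx = ~zero_su
        eta_a, su_a = eta[idx], su[idx][..., None]
        var = su_a**2
        # Newton for the mode of g(u) = kernel(eta + u) - u^2 / (2 var)
        u = np.zeros_like(eta_a)
        if family == "poisson":
            for _ in range(10):
                lam = j * np.exp(eta_a + u)
                grad = s - lam - u / var
                hess = -lam - 1.0 / var
                step = grad / hess
                u = np.clip(u - np.clip(step, -4.0, 4.0), -30.0, 30.0)
        else:
            a = alpha[idx][..., None]
            r = j * a
            for _ in range(10):
                m = j * np.exp(eta_a + u)
                grad = (s * r - r * m) / (r + m) - u / var  # d/du of NB kernel
                hess = -r * m * (r + s) / (r + m) ** 2 - 1.0 / var
                u = np.clip(u - np.clip(grad / hess, -4.0, 4.0), -30.0, 30.0)
        if family == "poisson":
            lam = j * np.exp(eta_a + u)
            curv = lam + 1.0 / var
        else:
            m = j * np.exp(eta_a + u)
            curv = r * m * (r + s) / (r + m) ** 2 + 1.0 / var
        tau = 1.0 / np.sqrt(curv)
        nodes = u[..., None] + np.sqrt(2.0) * tau[..., None] * _GH_NODES  # (..., n, K)
        if family == "poisson":
            log_f = _log_kernel_poisson(s[:, None], j, eta_a[..., None] + nodes)
        else:
            log_f = _log_kernel_negbin(s[:, None], j, eta_a[..., None] + nodes, a[..., None])
        log_f = log_f - nodes**2 / (2.0 * var[..., None]) - 0.5 * np.log(2.0 * np.pi * var[..., None])
        log_int = logsumexp(
            log_f + _GH_NODES**2 + _LOG_GH_WEIGHTS, axis=-1
        ) + np.log(np.sqrt(2.0)) + np.log(tau)
        out[idx] = log_int.sum(axis=-1)
    # exact weekly-total pmf needs the theta-free constant -sum_i log s_i!
    # (day-split multinomial constants cancel in every model comparison)
    const = -gammaln(s + 1.0).sum()
    return float(out[0] + const) if squeeze else out + const


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, loc, scale):
    return -_LOG_SQRT_2PI - np.log(scale) - 0.5 * ((x - loc) / scale) ** 2


def log_prior(theta: np.ndarray, priors: Priors) -> np.ndarray:
    theta = np.atleast_2d(theta)
    b0, bb, bt, su = theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3]
    lp = (
        _norm_logpdf(b0, priors.beta0_loc, priors.beta0_scale)
        + _norm_logpdf(bb, priors.beta_base_loc, priors.beta_base_scale)
        + _norm_logpdf(bt, priors.beta_treat_loc, priors.beta_treat_scale)
    )
    # Half-Normal(sigma_u_scale) on sigma_u
    half = np.where(
        su >= 0,
        np.log(2.0) + _norm_logpdf(np.abs(su), 0.0, priors.sigma_u_scale),
        -np.inf,
    )
    return lp + half


def log_posterior(theta, data: ModelData, priors: Priors, family: str = "poisson"):
    lp = log_prior(theta, priors)
    out = np.full_like(lp, -np.inf, dtype=float)
    ok = np.isfinite(lp)
    if np.any(ok):
        th = np.atleast_2d(theta)[ok]
        out[ok] = lp[ok] + marginal_loglik(th, data, family=family)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

PARAM_NAMES = ("beta0", "beta_base", "beta_treat", "sigma_u")


@dataclass
class PosteriorFit:
    """Posterior draws of the model parameters plus chain diagnostics."""

    draws: dict                     # name -> (chain, draw) arrays
    data: ModelData
    priors: Priors
    method: str                     # "mcmc" or "laplace"
    diagnostics: dict               # rhat / ess per parameter, divergences
    map_estimate: dict | None = None
    laplace_cov: np.ndarray | None = None
    family: str = "poisson"

    def flat(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.flat("beta_treat").size

    @property
    def ok(self) -> bool:
        rhats = self.diagnostics.get("rhat", {})
        return all(r <= 1.01 for r in rhats.values())

    def beta_treat_normal_approx(self) -> tuple[float, float]:
        """(mean, sd) of the marginal posterior of the treatment coefficient."""
        d = self.flat("beta_treat")
        return float(d.mean()), float(d.std(ddof=1))

    def conditional_intercepts(self) -> np.ndarray:
        """E[u_i | data] at the posterior mean of the shared parameters."""
        theta = np.array([self.flat(p).mean() for p in PARAM_NAMES])
        return _conditional_u(theta, self.data)

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior={k: np.asarray(v) for k, v in self.draws.items()})


def _conditional_u(theta: np.ndarray, data: ModelData) -> np.ndarray:
    """Posterior mean of each random intercept given shared parameters."""
    b0, bb, bt, su = theta
    eta = b0 + bb * data.x + bt * data.treat
    if su <= 1e-12:
        return np.zeros(data.n)
    grid = np.linspace(-5 * su, 5 * su, 201)
    log_w = (
        _log_kernel_poisson(data.totals[:, None], float(DIARY_DAYS), eta[:, None] + grid)
        - grid**2 / (2 * su**2)
    )
    w = np.exp(log_w - log_w.max(axis=1, keepdims=True))
    return (w * grid).sum(axis=1) / w.sum(axis=1)


def _batched_neg_logpost(data, priors, family):
    """Vectorised negative log-posterior in the unconstrained (log sigma_u) space."""

    def f(zb):
        zb = np.atleast_2d(zb)
        theta = np.column_stack([zb[:, 0], zb[:, 1], zb[:, 2], np.exp(zb[:, 3])])
        return -(log_posterior(theta, data, priors, family) + zb[:, 3])

    return f


def _fd_grad(fb, z, h=1e-6):
    # one batched call per gradient keeps optimisation cheap in simulations
    pts = np.vstack([z[None, :], z[None, :] + np.eye(len(z)) * h])
    vals = fb(pts)
    return (vals[1:] - vals[0]) / h


def _neg_logpost_unconstrained(z, data, priors, family):
    # z = (b0, b_base, b_treat, log sigma_u); include the Jacobian d sigma/d log sigma
    return float(_batched_neg_logpost(data, priors, family)(z[None, :])[0])


def _laplace_fit(data, priors, family, rng, n_sample=4000, z0=None):
    if z0 is None:
        start_b0 = np.log(max(data.totals.mean() / DIARY_DAYS, 0.05))
        z0 = np.array([start_b0, 0.0, 0.0, np.log(0.5)])
    fb = _batched_neg_logpost(data, priors, family)
    res = minimize(
        lambda z: float(fb(z[None, :])[0]), z0, jac=lambda z: _fd_grad(fb, z),
        method="BFGS", options={"gtol": 1e-6, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        res = minimize(
            lambda z: float(fb(z[None, :])[0]), z0,
            method="Nelder-Mead", options={"maxiter": 2000},
        )
    z_map = res.x
    hess = _numeric_hessian_batch(fb, z_map)
    try:
        cov = np.linalg.inv(hess)
        # symmetrise and guard against tiny negative eigenvalues
        cov = (cov + cov.T) / 2
        evals, evecs = np.linalg.eigh(cov)
        cov = (evecs * np.maximum(evals, 1e-10)) @ evecs.T
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(4, 1e-4))
    z_draws = rng.multivariate_normal(z_map, cov, size=n_sample)
    draws = {
        "beta0": z_draws[:, 0][None, :],
        "beta_base": z_draws[:, 1][None, :],
        "beta_treat": z_draws[:, 2][None, :],
        "sigma_u": np.exp(z_draws[:, 3])[None, :],
    }
    diagnostics = {
        "rhat": {p: 1.0 for p in PARAM_NAMES},
        "ess": {p: float(n_sample) for p in PARAM_NAMES},
        "divergences": 0,
        "optimizer_converged": bool(res.success),
    }
    map_est = dict(zip(PARAM_NAMES, [z_map[0], z_map[1], z_map[2], float(np.exp(z_map[3]))]))
    return PosteriorFit(
        draws=draws, data=data, priors=priors, method="laplace",
        diagnostics=diagnostics, map_estimate=map_est, laplace_cov=cov, family=family,
    )


def _numeric_hessian_batch(fb, x, eps=1e-4):
    """Central-difference Hessian, all perturbed points in one vectorised call."""
    n = len(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    pts = []
    pairs = [(i, k) for i in range(n) for k in range(i, n)]
    for i, k in pairs:
        ei = np.zeros(n); ei[i] = steps[i]
        ek = np.zeros(n); ek[k] = steps[k]
        pts.extend([x + ei + ek, x + ei - ek, x - ei + ek, x - ei - ek])
    vals = fb(np.asarray(pts))
    h = np.zeros((n, n))
    for idx, (i, k) in enumerate(pairs):
        fpp, fpm, fmp, fmm = vals[4 * idx: 4 * idx + 4]
        h[i, k] = h[k, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[k])
    return h


def _numeric_hessian(f, x, eps=1e-4):
    """Hessian of a scalar function (wrapper over the batched version)."""
    return _numeric_hessian_batch(lambda pts: np.array([f(p) for p in pts]), x, eps)


def independence_mh(
    log_q,
    centre: np.ndarray,
    cov: np.ndarray,
    rng: np.random.Generator,
    n_chains: int = 4,
    n_burn: int = 300,
    n_draws: int = 1500,
    df: float = 4.0,
    proposal_scale: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Independence Metropolis-Hastings with a mixture-of-t proposal.

    ``log_q`` is a batched unnormalised log-density; the proposal mixes a
    heavy-tailed t centred on ``centre`` with a 3x-inflated component
    (weights 0.8/0.2), so tails the Laplace fit under-estimates stay covered
    and chains cannot stick.  A rough Laplace fit only lowers acceptance.
    Returns chains of shape (n_chains, n_draws, dim) and the acceptance
    fraction.
    """
    dim = len(centre)
    cov = proposal_scale * ((cov + cov.T) / 2) + 1e-12 * np.eye(dim)
    comps = (multivariate_t(centre, cov, df=df),
             multivariate_t(centre, 9.0 * cov, df=df))
    weights = np.array([0.8, 0.2])
    log_w = np.log(weights)

    def draw(k):
        which = rng.random(k) < weights[1]
        out = np.atleast_2d(np.asarray(comps[0].rvs(size=k, random_state=rng)))
        if which.any():
            wide = np.atleast_2d(np.asarray(comps[1].rvs(size=k, random_state=rng)))
            out[which] = wide[which]
        return out

    def log_t(x):
        return np.logaddexp(log_w[0] + comps[0].logpdf(x), log_w[1] + comps[1].logpdf(x))

    cur = draw(n_chains)
    lq_cur = np.asarray(log_q(cur))
    lt_cur = np.atleast_1d(log_t(cur))
    chains = np.empty((n_chains, n_draws, dim))
    accepted = 0
    for step in range(n_burn + n_draws):
        prop = draw(n_chains)
        lq_p = np.asarray(log_q(prop))
        lt_p = np.atleast_1d(log_t(prop))
        with np.errstate(invalid="ignore"):
            acc = np.log(rng.random(n_chains)) < (lq_p - lt_p) - (lq_cur - lt_cur)
        acc &= np.isfinite(lq_p)
        cur[acc] = prop[acc]
        lq_cur[acc] = lq_p[acc]
        lt_cur[acc] = lt_p[acc]
        if step >= n_burn:
            chains[:, step - n_burn] = cur
            accepted += int(acc.sum())
    return chains, accepted / (n_chains * n_draws)


def _diagnose(draws: dict) -> dict:
    idata = az.from_dict(posterior={k: np.asarray(v) for k, v in draws.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    return {
        "rhat": {p: float(rhat[p].values) for p in draws},
        "ess": {p: float(ess[p].values) for p in draws},
        "divergences": 0,
    }


def fit_poisson_glmm(
    data: ModelData,
    priors: Priors | None = None,
    rng: np.random.Generator | None = None,
    method: str = "mcmc",
    family: str = "poisson",
    n_chains: int = 4,
    n_burn: int = 300,
    n_draws: int = 1500,
    z0: np.ndarray | None = None,
) -> PosteriorFit:
    """Fit the Bayesian Poisson (or negative-binomial) mixed model.

    ``method="mcmc"`` runs independence MH on the marginal posterior (proposal
    built from the Laplace fit); ``method="laplace"`` returns the fast normal
    approximation used by the sequential monitor and operating-characteristic
    simulations.  ``z0`` optionally warm-starts the mode search (unconstrained
    scale, log sigma_u last).  Deterministic given ``rng``'s seed.
    """
    priors = priors or Priors()
    rng = rng or np.random.default_rng()
    if family not in ("poisson", "negbin"):
        raise ValueError(f"unknown family {family!r}")
    if family == "negbin":
        return _fit_negbin(data, priors, rng, n_chains, n_burn, n_draws)
    if method == "laplace":
        return _laplace_fit(data, priors, family, rng, z0=z0)
    if method != "mcmc":
        raise ValueError(f"unknown method {method!r}")

    lap = _laplace_fit(data, priors, family, rng, z0=z0)
    centre = np.array([lap.map_estimate[p] for p in PARAM_NAMES])
    centre[3] = np.log(max(centre[3], 1e-4))   # unconstrained: log sigma_u

    def log_q(z):
        z = np.atleast_2d(z)
        theta = np.column_stack([z[:, 0], z[:, 1], z[:, 2], np.exp(z[:, 3])])
        return log_posterior(theta, data, priors, family) + z[:, 3]

    # pilot run, then a moment-matched proposal: the Laplace covariance can
    # under-estimate posterior spread (skew), which makes chains sticky
    pilot, _ = independence_mh(
        log_q, centre, lap.laplace_cov, rng, n_chains=2, n_burn=100, n_draws=400,
    )
    flat_pilot = pilot.reshape(-1, 4)
    centre = flat_pilot.mean(axis=0)
    prop_cov = np.cov(flat_pilot.T)

    # sample; if split-R-hat misses the 1.01 gate, extend the run (twice at most)
    draws_target = n_draws
    for attempt in range(3):
        chains, acc = independence_mh(
            log_q, centre, prop_cov, rng,
            n_chains=n_chains, n_burn=n_burn, n_draws=draws_target,
            proposal_scale=1.1,
        )
        draws = {p: chains[:, :, i] for i, p in enumerate(PARAM_NAMES)}
        draws["sigma_u"] = np.exp(chains[:, :, 3])
        diagnostics = _diagnose(draws)
        diagnostics["acceptance_fraction"] = acc
        if max(diagnostics["rhat"].values()) <= 1.01:
            break
        draws_target *= 2
    return PosteriorFit(
        draws=draws, data=data, priors=priors, method="mcmc",
        diagnostics=diagnostics, map_estimate=lap.map_estimate,
        laplace_cov=lap.laplace_cov, family=family,
    )


def _fit_negbin(data, priors, rng, n_chains, n_burn, n_draws):
    """Negative-binomial sensitivity variant: extra log-dispersion parameter."""

    def log_q(z):
        z = np.atleast_2d(z)
        theta4 = np.column_stack([z[:, 0], z[:, 1], z[:, 2], np.exp(z[:, 3])])
        log_alpha = z[:, 4]
        lp = log_prior(theta4, priors) + norm.logpdf(log_alpha, 1.0, 1.5) + z[:, 3]
        out = np.full(lp.shape, -np.inf)
        ok = np.isfinite(lp)
        if ok.any():
            out[ok] = lp[ok] + marginal_loglik(
                theta4[ok], data, family="negbin", alpha=np.exp(log_alpha[ok])
            )
        return out

    start_b0 = np.log(max(data.totals.mean() / DIARY_DAYS, 0.05))
    z0 = np.array([start_b0, 0.0, 0.0, np.log(0.5), 1.5])
    res = minimize(lambda z: -log_q(z[None, :])[0], z0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    hess = _numeric_hessian(lambda z: -log_q(z[None, :])[0], res.x)
    try:
        cov = np.linalg.inv((hess + hess.T) / 2)
        evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
        cov = (evecs * np.maximum(evals, 1e-10)) @ evecs.T
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(5, 1e-3))
    chains, acc = independence_mh(
        log_q, res.x, cov, rng, n_chains=n_chains, n_burn=n_burn, n_draws=n_draws
    )
    names = PARAM_NAMES + ("log_alpha",)
    draws = {p: chains[:, :, i] for i, p in enumerate(names)}
    draws["sigma_u"] = np.exp(chains[:, :, 3])
    diagnostics = _diagnose(draws)
    diagnostics["acceptance_fraction"] = acc
    return PosteriorFit(
        draws=draws, data=data, priors=priors, method="mcmc",
        diagnostics=diagnostics, family="negbin",
    )


# ---------------------------------------------------------------------------
# summaries, predictive checks, outliers, sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means, equal-tailed 95% credible intervals, and the rate ratio."""

    params: dict
    beta_treat_mean: float
    beta_treat_ci: tuple[float, float]
    rate_ratio: float

    def __str__(self) -> str:
        lo, hi = self.beta_treat_ci
        return (
            f"beta_treat posterior mean {self.beta_treat_mean:.2f} "
            f"(95% CrI {lo:.2f}, {hi:.2f}); rate ratio {self.rate_ratio:.2f}"
        )


def summarize_posterior(fit: PosteriorFit, force: bool = False) -> PosteriorSummary:
    """Equal-tailed summaries; refuses (with the report) if diagnostics failed."""
    if not fit.ok and not force:
        raise DiagnosticError("chain diagnostics failed (split-R-hat > 1.01)",
                              fit.diagnostics)
    params = {}
    for p in fit.draws:
        d = fit.flat(p)
        lo, hi = np.quantile(d, [0.025, 0.975])
        params[p] = ParamSummary(float(d.mean()), float(d.std(ddof=1)), float(lo), float(hi))
    bt = params["beta_treat"]
    return PosteriorSummary(
        params=params,
        beta_treat_mean=bt.mean,
        beta_treat_ci=(bt.ci_low, bt.ci_high),
        rate_ratio=float(np.exp(bt.mean)),
    )


def posterior_predictive_check(
    fit: PosteriorFit,
    data: ModelData | None = None,
    n_rep: int = 500,
    rng: np.random.Generator | None = None,
) -> dict:
    """Predictive p-values P(T_rep >= T_obs) for arm-wise weekly-total statistics.

    Statistics: mean, variance and zero-count fraction of the weekly totals in
    each arm.  Values near 0 or 1 indicate misfit of that feature.
    """
    data = data or fit.data
    rng = rng or np.random.default_rng()
    idx = rng.integers(fit.n_draws, size=n_rep)
    b0 = fit.flat("beta0")[idx]
    bb = fit.flat("beta_base")[idx]
    bt = fit.flat("beta_treat")[idx]
    su = fit.flat("sigma_u")[idx]

    arms = {"immediate": data.treat == 1, "delayed": data.treat == 0}
    stats_obs = {
        (arm, stat): val
        for arm, m in arms.items()
        for stat, val in (
            ("mean", data.totals[m].mean()),
            ("var", data.totals[m].var(ddof=1)),
            ("zero_frac", float((data.totals[m] == 0).mean())),
        )
    }
    greater = {k: 0 for k in stats_obs}
    equal = {k: 0 for k in stats_obs}
    for r in range(n_rep):
        u = rng.normal(0.0, su[r], size=data.n)
        lam = np.exp(b0[r] + bb[r] * data.x + bt[r] * data.treat + u)
        totals = rng.poisson(DIARY_DAYS * lam)
        for arm, m in arms.items():
            rep = {
                "mean": totals[m].mean(),
                "var": totals[m].var(ddof=1),
                "zero_frac": float((totals[m] == 0).mean()),
            }
            for stat in ("mean", "var", "zero_frac"):
                if rep[stat] > stats_obs[(arm, stat)]:
                    greater[(arm, stat)] += 1
                elif rep[stat] == stats_obs[(arm, stat)]:
                    equal[(arm, stat)] += 1
    # mid-p convention keeps discrete statistics (zero fractions) calibrated
    return {f"{arm}_{stat}": (greater[k] + 0.5 * equal[k] + 0.5) / (n_rep + 1.0)
            for k in stats_obs for arm, stat in [k]}


@dataclass(frozen=True)
class OutlierReport:
    flagged: list[str]
    residuals: np.ndarray
    cooks: np.ndarray
    leverage: np.ndarray
    thresholds: dict


def detect_outliers(
    fit: PosteriorFit,
    data: ModelData | None = None,
    resid_threshold: float = 3.0,
    cooks_multiple: float = 4.0,
    leverage_multiple: float = 2.0,
) -> OutlierReport:
    """Flag influential observations: large residuals plus influence measures.

    Residuals are marginal (population-level) Pearson residuals of the weekly
    totals: the fitted mean integrates the random intercept out and the
    variance carries the lognormal overdispersion, so a participant far from
    their arm-and-baseline peers stands out rather than being absorbed into
    their own intercept.  Cook's distance and leverage come from a
    fixed-effects Poisson regression approximation (statsmodels GLM).  A
    participant is flagged when the residual is large *and* either Cook's
    distance (> cooks_multiple / n) or leverage (> leverage_multiple * (p+1)/n)
    is large.  Set thresholds to infinity to disable flagging.
    """
    import statsmodels.api as sm

    data = data or fit.data
    theta = np.array([fit.flat(p).mean() for p in PARAM_NAMES])
    su2 = theta[3] ** 2
    mean = DIARY_DAYS * np.exp(
        theta[0] + theta[1] * data.x + theta[2] * data.treat + su2 / 2
    )
    var = mean + (np.exp(su2) - 1.0) * mean**2   # Poisson-lognormal total variance
    resid = (data.totals - mean) / np.sqrt(var)

    exog = sm.add_constant(np.column_stack([data.x, data.treat]))
    glm = sm.GLM(data.totals, exog, family=sm.families.Poisson(),
                 exposure=np.full(data.n, float(DIARY_DAYS)))
    glm_res = glm.fit()
    infl = glm_res.get_influence()
    cooks = np.asarray(infl.cooks_distance[0])
    leverage = np.asarray(infl.hat_matrix_diag)

    n, p = data.n, 2
    thr = {
        "residual": resid_threshold,
        "cooks": cooks_multiple / n,
        "leverage": leverage_multiple * (p + 1) / n,
    }
    mask = (np.abs(resid) > thr["residual"]) & (
        (cooks > thr["cooks"]) | (leverage > thr["leverage"])
    )
    flagged = [data.participant_ids[i] for i in np.flatnonzero(mask)]
    return OutlierReport(flagged, resid, cooks, leverage, thr)


def sensitivity_suite(
    data: ModelData,
    variants: list[dict],
    rng: np.random.Generator,
    method: str = "mcmc",
    **fit_kwargs,
) -> "pd.DataFrame":
    """Refit under prior / model / data variants and tabulate the summaries.

    Each variant dict has a ``name`` plus any of: ``priors`` (a Priors),
    ``family`` ("poisson" or "negbin"), ``subset`` (bool mask over rows).
    A failing variant is recorded as a failed row; the suite continues.
    Returns the table plus the maximum pairwise difference of beta_treat
    posterior means in ``df.attrs["max_pairwise_diff"]``.
    """
    import pandas as pd

    rows = []
    means = []
    for var in variants:
        name = var.get("name", "variant")
        seed = int(rng.integers(2**31))
        try:
            sub = var.get("subset")
            d = data if sub is None else ModelData(
                totals=data.totals[sub],
                baseline_totals=data.baseline_totals[sub],
                treat=data.treat[sub],
                day_counts=data.day_counts[sub],
                participant_ids=[pid for pid, keep in zip(data.participant_ids, sub) if keep],
            )
            fit = fit_poisson_glmm(
                d,
                priors=var.get("priors"),
                rng=np.random.default_rng(seed),
                method=var.get("method", method),
                family=var.get("family", "poisson"),
                **fit_kwargs,
            )
            s = summarize_posterior(fit)
            rows.append({
                "variant": name, "status": "ok", "n": d.n,
                "beta_treat_mean": s.beta_treat_mean,
                "ci_low": s.beta_treat_ci[0], "ci_high": s.beta_treat_ci[1],
                "rate_ratio": s.rate_ratio,
            })
            means.append(s.beta_treat_mean)
        except (DiagnosticError, ValueError, np.linalg.LinAlgError) as err:
            rows.append({"variant": name, "status": f"failed: {err}", "n": np.nan,
                         "beta_treat_mean": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "rate_ratio": np.nan})
    df = pd.DataFrame(rows)
    df.attrs["max_pairwise_diff"] = (
        float(max(means) - min(means)) if len(means) >= 2 else np.nan
    )
    return df
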