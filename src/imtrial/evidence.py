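"""Directional Bayes factors on the treatment coefficient and sequential monitoring.

The trial's stopping logic compares one-sided hypotheses on the treatment
log-rate coefficient against the point null of no difference:

* ``positive_effect``: b_treat < 0 - the immediate arm has *fewer* IMs;
* ``negative_effect``: b_treat > 0 - the intervention makes things worse.

The default Bayes factor is a one-sided Savage-Dickey density ratio computed
from the encompassing fit: BF(H_dir : H0) equals the prior-to-posterior density
ratio at zero times the posterior-to-prior odds of the direction's half-line.
Bridge sampling of the marginal likelihoods (truncated-prior model vs null
model) is provided as an independent cross-check.

At each interim look the monitor first screens for evidence of harm
(``negative_effect``); only if that Bayes factor stays below the threshold is
the efficacy Bayes factor computed.  Crossing the threshold (20 by default)
stops the trial; otherwise monitoring continues to the recruitment ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gaussian_kde, multivariate_normal, norm

from .config import DesignConfig, Priors
from .data import ParticipantRecord, TrialDataset
from .glmm import (
    ModelData,
    PosteriorFit,
    build_model_data,
    fit_poisson_glmm,
    log_posterior,
    marginal_loglik,
)

DIRECTIONS = ("positive_effect", "negative_effect")
_TINY_DENSITY = 1e-300


@dataclass(frozen=True)
class BayesFactorResult:
    """BF(H_direction : H0), finite and positive."""

    bf: float
    direction: str
    method: str
    n: int
    flagged: bool = False   # True when the posterior density at 0 underflowed
    details: dict = field(default_factory=dict)

    @property
    def log10(self) -> float:
        return float(np.log10(self.bf))

    @property
    def reciprocal(self) -> float:
        """BF(H0 : H_direction) - evidence *against* the directional hypothesis."""
        return 1.0 / self.bf


def savage_dickey_onesided(
    post_density0: float,
    post_mass_dir: float,
    prior_loc: float,
    prior_scale: float,
    direction: str,
) -> float:
    """One-sided Savage-Dickey ratio from posterior density/mass at and around 0.

    BF(H_dir : H0) = [prior(0) / posterior(0)] * [P_post(dir) / P_prior(dir)],
    the encompassing-prior identity for a half-line alternative against the
    point null nested at 0.
    """
    prior0 = norm.pdf(0.0, prior_loc, prior_scale)
    if direction == "positive_effect":
        prior_mass = norm.cdf(0.0, prior_loc, prior_scale)  # P(b_treat < 0) a priori
    elif direction == "negative_effect":
        prior_mass = norm.sf(0.0, prior_loc, prior_scale)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return (prior0 / post_density0) * (post_mass_dir / prior_mass)


def bf_directional(
    fit: PosteriorFit,
    direction: str,
    method: str = "savage_dickey",
    density: str = "normal",
    rng: Optional[np.random.Generator] = None,
) -> BayesFactorResult:
    """Directional Bayes factor for the treatment coefficient.

    ``density="normal"`` (default) uses a normal approximation to the marginal
    posterior of b_treat; ``density="kde"`` uses a Gaussian kernel density on
    the draws.  ``method="bridge"`` instead bridge-samples the marginal
    likelihoods of the truncated-prior and null models.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if not fit.ok:
        raise RuntimeError("refusing to compute a Bayes factor from a failed fit")
    if method == "bridge":
        return _bf_bridge(fit, direction, rng)
    if method != "savage_dickey":
        raise ValueError(f"unknown method {method!r}")

    priors = fit.priors
    m, s = fit.beta_treat_normal_approx()
    if density == "normal":
        post0 = norm.pdf(0.0, m, s)
        post_mass = norm.cdf(0.0, m, s) if direction == "positive_effect" else norm.sf(0.0, m, s)
    elif density == "kde":
        draws = fit.flat("beta_treat")
        kde = gaussian_kde(draws)
        post0 = float(kde(0.0)[0])
        frac = float((draws < 0).mean())
        post_mass = frac if direction == "positive_effect" else 1.0 - frac
    else:
        raise ValueError(f"unknown density {density!r}")

    flagged = post0 < _TINY_DENSITY or post_mass <= 0
    post0 = max(post0, _TINY_DENSITY)
    post_mass = max(post_mass, _TINY_DENSITY)
    bf = savage_dickey_onesided(
        post0, post_mass, priors.beta_treat_loc, priors.beta_treat_scale, direction
    )
    return BayesFactorResult(
        bf=float(bf), direction=direction, method="savage_dickey", n=fit.data.n,
        flagged=bool(flagged),
        details={"post_mean": m, "post_sd": s, "post_density0": post0,
                 "post_mass": post_mass, "density": density},
    )


# ---------------------------------------------------------------------------
# bridge sampling cross-check
# ---------------------------------------------------------------------------

def log_marginal_bridge(
    draws: np.ndarray,
    log_q,
    rng: np.random.Generator,
    n_proposal: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> float:
    """Bridge-sampling estimate of log Z for an unnormalised density exp(log_q).

    ``draws`` are posterior samples (rows) on an unconstrained scale; the
    proposal is a moment-matched multivariate normal (Meng-Wong iteration with
    the optimal bridge function).
    """
    draws = np.atleast_2d(draws)
    n1 = draws.shape[0]
    n2 = n_proposal or n1
    mean = draws.mean(axis=0)
    cov = np.cov(draws.T) + 1e-10 * np.eye(draws.shape[1])
    g = multivariate_normal(mean, cov, allow_singular=True)
    prop = rng.multivariate_normal(mean, cov, size=n2)

    l1 = np.asarray(log_q(draws)) - g.logpdf(draws)      # at posterior draws
    l2 = np.asarray(log_q(prop)) - g.logpdf(prop)        # at proposal draws
    l2 = l2[np.isfinite(l2)]
    if l2.size == 0:
        raise RuntimeError("bridge proposal entirely outside the support")
    s1 = n1 / (n1 + l2.size)
    s2 = 1.0 - s1

    lz = logsumexp(l2) - np.log(l2.size)                 # importance-sampling start
    for _ in range(max_iter):
        log_num = logsumexp(l2 - np.logaddexp(np.log(s1) + l2, np.log(s2) + lz)) - np.log(l2.size)
        log_den = logsumexp(-np.logaddexp(np.log(s1) + l1, np.log(s2) + lz)) - np.log(n1)
        lz_new = log_num - log_den
        if abs(lz_new - lz) < tol:
            lz = lz_new
            break
        lz = lz_new
    return float(lz)


def _to_unconstrained(fit: PosteriorFit) -> np.ndarray:
    z = np.column_stack([
        fit.flat("beta0"), fit.flat("beta_base"), fit.flat("beta_treat"),
        np.log(np.maximum(fit.flat("sigma_u"), 1e-10)),
    ])
    return z


def _bf_bridge(fit: PosteriorFit, direction: str, rng) -> BayesFactorResult:
    """BF via marginal likelihoods: truncated-prior model vs the null model.

    The truncated model's evidence equals the encompassing evidence times the
    posterior/prior mass ratio on the half-line, so only the encompassing and
    null evidences need bridge estimates.
    """
    rng = rng or np.random.default_rng()
    priors, data = fit.priors, fit.data

    z_enc = _to_unconstrained(fit)
    n_keep = min(len(z_enc), 4000)
    sel = rng.choice(len(z_enc), size=n_keep, replace=False)
    z_enc = z_enc[sel]

    def log_q_enc(z):
        z = np.atleast_2d(z)
        theta = np.column_stack([z[:, 0], z[:, 1], z[:, 2], np.exp(z[:, 3])])
        return log_posterior(theta, data, priors) + z[:, 3]

    lz_enc = log_marginal_bridge(z_enc, log_q_enc, rng)

    null_draws, log_q_null = _fit_null_model(data, priors, rng)
    lz_null = log_marginal_bridge(null_draws, log_q_null, rng)

    bt = fit.flat("beta_treat")
    frac_neg = float((bt < 0).mean())
    post_mass = frac_neg if direction == "positive_effect" else 1.0 - frac_neg
    prior_mass = (
        norm.cdf(0.0, priors.beta_treat_loc, priors.beta_treat_scale)
        if direction == "positive_effect"
        else norm.sf(0.0, priors.beta_treat_loc, priors.beta_treat_scale)
    )
    post_mass = max(post_mass, 1.0 / (len(bt) + 1))
    log_bf = lz_enc - lz_null + np.log(post_mass) - np.log(prior_mass)
    return BayesFactorResult(
        bf=float(np.exp(log_bf)), direction=direction, method="bridge", n=data.n,
        details={"log_z_encompassing": lz_enc, "log_z_null": lz_null,
                 "post_mass": post_mass},
    )


def _fit_null_model(data: ModelData, priors: Priors, rng):
    """Independence-MH run on the 3-parameter null model (b_treat = 0)."""
    from scipy.optimize import minimize

    from .glmm import _numeric_hessian, independence_mh

    def log_q(z):
        z = np.atleast_2d(z)
        theta = np.column_stack([
            z[:, 0], z[:, 1], np.zeros(len(z)), np.exp(z[:, 2]),
        ])
        lp = (
            norm.logpdf(z[:, 0], priors.beta0_loc, priors.beta0_scale)
            + norm.logpdf(z[:, 1], priors.beta_base_loc, priors.beta_base_scale)
            + np.log(2.0) + norm.logpdf(np.exp(z[:, 2]), 0.0, priors.sigma_u_scale)
            + z[:, 2]   # Jacobian of sigma_u = exp(z)
        )
        return lp + marginal_loglik(theta, data)

    start = np.array([np.log(max(data.totals.mean() / 7.0, 0.05)), 0.0, np.log(0.5)])
    res = minimize(lambda z: -log_q(z[None, :])[0], start, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    hess = _numeric_hessian(lambda z: -log_q(z[None, :])[0], res.x)
    try:
        cov = np.linalg.inv((hess + hess.T) / 2)
        evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
        cov = (evecs * np.maximum(evals, 1e-10)) @ evecs.T
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(3, 1e-3))
    chains, _ = independence_mh(log_q, res.x, cov, rng, n_chains=4, n_burn=200, n_draws=700)
    return chains.reshape(-1, 3), log_q


# ---------------------------------------------------------------------------
# sequential monitoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LookRecord:
    n: int
    bf_negative: Optional[float]
    bf_positive: Optional[float]
    decision: str                    # continue / stop_negative / stop_positive / max_reached


@dataclass
class EvidenceTrace:
    """Per-look Bayes factors and the stop/continue decisions, for audit."""

    looks: list[LookRecord] = field(default_factory=list)
    warning: Optional[str] = None

    @property
    def decision(self) -> str:
        if not self.looks:
            return "inconclusive"
        return self.looks[-1].decision

    @property
    def stopped_early(self) -> bool:
        return self.decision in ("stop_negative", "stop_positive")

    @property
    def n_at_decision(self) -> Optional[int]:
        return self.looks[-1].n if self.looks else None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(l) for l in self.looks])
        if len(df):
            df["log10_bf_pos"] = np.log10(df["bf_positive"].astype(float))
        return df


def sequential_monitor(
    stream: TrialDataset | Sequence[ParticipantRecord],
    design: DesignConfig,
    rng: np.random.Generator,
) -> EvidenceTrace:
    """Run the interim-look schedule over an outcome-completion-ordered stream.

    At each look the first ``n`` completers are analysed with the design's fit
    method and priors.  The harm check (``negative_effect``) gates the efficacy
    check; either Bayes factor exceeding the threshold stops the trial.  The
    full trace is returned regardless of stopping.
    """
    if isinstance(stream, TrialDataset):
        recs = stream.by_completion_order(design.min_observed_days)
    else:
        recs = list(stream)
    trace = EvidenceTrace()
    if len(recs) < design.first_look:
        trace.warning = (
            f"only {len(recs)} completers available, fewer than the first look "
            f"({design.first_look}); no analyses run"
        )
        return trace

    warm_start = None
    for n in design.look_schedule(len(recs)):
        # records are only read here, so the subset shares them (no deep copy)
        subset = TrialDataset(sorted(recs[:n], key=lambda r: r.enrollment_index))
        try:
            data = build_model_data(subset, design.min_observed_days)
        except ValueError as err:   # e.g. single-arm data at a tiny look
            warnings.warn(f"look at n={n} skipped: {err}", stacklevel=2)
            trace.looks.append(LookRecord(n, None, None, "continue"))
            continue
        fit = fit_poisson_glmm(
            data, priors=design.priors, rng=np.random.default_rng(int(rng.integers(2**31))),
            method=design.fit_method, n_chains=design.n_chains,
            n_burn=design.n_burn, n_draws=design.n_draws, z0=warm_start,
        )
        if fit.map_estimate is not None:
            warm_start = np.array([
                fit.map_estimate["beta0"], fit.map_estimate["beta_base"],
                fit.map_estimate["beta_treat"],
                np.log(max(fit.map_estimate["sigma_u"], 1e-4)),
            ])
        bf_neg = bf_directional(fit, "negative_effect", method=design.bf_method)
        if bf_neg.bf > design.bf_threshold:
            trace.looks.append(LookRecord(n, bf_neg.bf, None, "stop_negative"))
            return trace
        bf_pos = bf_directional(fit, "positive_effect", method=design.bf_method)
        if bf_pos.bf > design.bf_threshold:
            trace.looks.append(LookRecord(n, bf_neg.bf, bf_pos.bf, "stop_positive"))
            return trace
        trace.looks.append(LookRecord(n, bf_neg.bf, bf_pos.bf, "continue"))

    if trace.looks and len(recs) >= design.n_max:
        last = trace.looks[-1]
        trace.looks[-1] = LookRecord(last.n, last.bf_negative, last.bf_positive, "max_reached")
    return trace
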