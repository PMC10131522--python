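"""Synthetic diary-count trial data with the structure the analysis assumes.

Each participant contributes a 7-day baseline diary and (once randomised) a
7-day week-4 diary of Poisson counts.  Participant heterogeneity enters through
a lognormal random intercept; the immediate arm's week-4 log-rate additionally
carries the treatment effect, and both arms share a secular trend.  Latent
truth (intercepts, rates, pre-masking counts) is stored on each record so that
downstream stages can be tested against ground truth.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigurationError, GeneratorConfig
from .data import DIARY_DAYS, DailyDiarySeries, ParticipantRecord, TrialDataset


def _validate(cfg: GeneratorConfig) -> None:
    if not isinstance(cfg, GeneratorConfig):
        raise ConfigurationError("cfg must be a GeneratorConfig")


def daily_rate(cfg: GeneratorConfig, u: float, phase: str, arm: str | None) -> float:
    """Expected daily count for one participant in one phase."""
    log_rate = cfg.beta0 + u
    if phase == "week4":
        log_rate += cfg.beta_trend
        if arm == "immediate":
            log_rate += cfg.beta_treat
    return float(np.exp(log_rate))


def generate_participant(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    enrollment_index: int = 0,
    participant_id: str | None = None,
) -> ParticipantRecord:
    """Draw one participant's baseline diary and latent state.

    The week-4 diary is *not* drawn here: it depends on the (not yet assigned)
    arm.  Use :func:`generate_week4` after randomisation.
    """
    _validate(cfg)
    u = float(rng.normal(0.0, cfg.sigma_u)) if cfg.sigma_u > 0 else 0.0
    base_rate = daily_rate(cfg, u, "baseline", None)
    base_counts = rng.poisson(base_rate, size=DIARY_DAYS).astype(float)
    rec = ParticipantRecord(
        participant_id=participant_id or f"P{enrollment_index:04d}",
        enrollment_index=enrollment_index,
        baseline=DailyDiarySeries("baseline", base_counts),
        latents={"u": u, "baseline_rate": base_rate},
    )
    rec.eligible = rec.baseline.observed_total() >= cfg.eligibility_floor
    return rec


def generate_week4(
    cfg: GeneratorConfig, rec: ParticipantRecord, rng: np.random.Generator
) -> ParticipantRecord:
    """Draw the week-4 diary for a randomised participant (in place)."""
    if rec.arm is None:
        raise ValueError("participant must be randomised before week-4 generation")
    rate = daily_rate(cfg, rec.latents["u"], "week4", rec.arm)
    counts = rng.poisson(rate, size=DIARY_DAYS).astype(float)
    rec.week4 = DailyDiarySeries("week4", counts)
    rec.latents["week4_rate"] = rate
    return rec


def generate_enrollment_stream(
    cfg: GeneratorConfig, n: int, rng: np.random.Generator
) -> TrialDataset:
    """Ordered stream of ``n`` enrolled participants, eligibility flagged.

    Ineligible participants (baseline total below the floor) and participants
    lost before randomisation are generated and flagged, not dropped, so that
    CONSORT tallies can be checked against the generator's own bookkeeping.
    No arms are assigned here; randomisation is a separate stage.
    """
    _validate(cfg)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > cfg.n_max:
        raise ValueError(f"n={n} exceeds cfg.n_max={cfg.n_max}")
    recs = []
    for i in range(n):
        rec = generate_participant(cfg, rng, enrollment_index=i)
        if rec.eligible and cfg.loss_rate > 0:
            rec.lost_pre_randomisation = bool(rng.random() < cfg.loss_rate)
        recs.append(rec)
    return TrialDataset(recs)


def inject_missingness(
    ds: TrialDataset, rate: float, rng: np.random.Generator
) -> TrialDataset:
    """Mark each observed diary day missing independently with probability ``rate``.

    Missingness is completely at random (MCAR).  The pre-masking counts are
    retained in each record's latents as ground truth for imputation tests.
    Returns a new dataset; the input is untouched.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = ds.copy()
    for rec in out:
        truth = {}
        for name in ("baseline", "week4"):
            series = getattr(rec, name)
            if series is None:
                continue
            truth[name] = series.values.copy()
            if rate > 0:
                mask = (rng.random(DIARY_DAYS) < rate) & ~series.missing
                series.values[mask] = np.nan
        rec.latents["true_counts"] = truth
    return out


def marginal_daily_mean(cfg: GeneratorConfig) -> float:
    """Closed-form marginal mean of a baseline daily count.

    Lognormal mixing of a Poisson rate: E[Y] = exp(beta0 + sigma_u^2 / 2).
    """
    return float(np.exp(cfg.beta0 + cfg.sigma_u**2 / 2))
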