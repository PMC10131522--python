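"""Design operating characteristics by end-to-end trial simulation.

Each replicate composes the whole pipeline: enrollment generation with
eligibility screening, minimisation randomisation (with the scheduled
allocation-percentage change), week-4 outcome generation, missing-day
injection, EM imputation, and the sequential Bayes-factor monitor.  Aggregating
replicate decisions gives the design's stopping probabilities and the
distribution of the sample size at decision; a fixed-n variant traces the
Bayes factor as a function of sample size for prospective planning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conduct import randomise_stream
from .config import DesignConfig, GeneratorConfig
from .data import TrialDataset
from .evidence import EvidenceTrace, bf_directional, sequential_monitor
from .glmm import build_model_data, fit_poisson_glmm
from .imputation import impute_dataset
from .synthetic import generate_enrollment_stream, generate_week4, inject_missingness


@dataclass(frozen=True)
class TrialOutcome:
    decision: str
    n_at_decision: int | None
    n_randomised: int
    final_bf_negative: float | None
    final_bf_positive: float | None
    trace: EvidenceTrace
    failed: bool = False
    error: str | None = None


def simulate_completer_stream(
    gen: GeneratorConfig,
    design: DesignConfig,
    n_completers: int,
    rng: np.random.Generator,
) -> TrialDataset:
    """Generate, randomise, mask and impute until ``n_completers`` have outcomes.

    Completion order equals enrollment order (diaries close 4 weeks after
    randomisation for everyone).  Over-enrolls to cover screening failures and
    pre-randomisation losses.
    """
    cfg_n = gen.n_max
    recs = []
    enrolled = 0
    completers = 0
    # keep generating until enough analysable participants exist
    while completers < n_completers:
        batch_size = max(8, int(1.5 * (n_completers - completers)))
        from .synthetic import generate_participant

        for _ in range(batch_size):
            rec = generate_participant(gen, rng, enrollment_index=enrolled)
            enrolled += 1
            if rec.eligible and gen.loss_rate > 0:
                rec.lost_pre_randomisation = bool(rng.random() < gen.loss_rate)
            recs.append(rec)
            if rec.eligible and not rec.lost_pre_randomisation:
                completers += 1
            if completers >= n_completers:
                break
    ds = TrialDataset(recs)
    ds, _ = randomise_stream(ds, design, rng)
    for i, rec in enumerate(ds):
        if rec.randomised:
            generate_week4(gen, rec, rng)
            rec.completion_index = i
    ds = inject_missingness(ds, gen.missing_rate, rng)
    if gen.missing_rate > 0:
        ds = impute_dataset(ds)
    return ds


def simulate_trial_once(
    design: DesignConfig, gen: GeneratorConfig, rng: np.random.Generator
) -> TrialOutcome:
    """One complete simulated trial with its full audit trace."""
    try:
        target = min(design.n_max, gen.n_max)
        ds = simulate_completer_stream(gen, design, target, rng)
        trace = sequential_monitor(ds, design, rng)
        last = trace.looks[-1] if trace.looks else None
        return TrialOutcome(
            decision=trace.decision,
            n_at_decision=trace.n_at_decision,
            n_randomised=len(ds.randomised()),
            final_bf_negative=None if last is None else last.bf_negative,
            final_bf_positive=None if last is None else last.bf_positive,
            trace=trace,
        )
    except Exception as err:  # propagated stage errors mark the trial failed
        return TrialOutcome(
            decision="failed", n_at_decision=None, n_randomised=0,
            final_bf_negative=None, final_bf_positive=None,
            trace=EvidenceTrace(), failed=True, error=str(err),
        )


@dataclass(frozen=True)
class OCReport:
    """Stopping probabilities and sample-size-at-decision distribution."""

    p_stop_positive: float
    p_stop_negative: float
    p_max_reached: float
    n_mean: float
    n_median: float
    n_q25: float
    n_q75: float
    reps: int
    n_failed: int
    effect: float
    valid: bool

    def as_dict(self) -> dict:
        return dict(vars(self))


def operating_characteristics(
    design: DesignConfig,
    gen: GeneratorConfig,
    reps: int,
    rng: np.random.Generator,
) -> OCReport:
    """Aggregate ``reps`` independent simulated trials into an OC report."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    outcomes = []
    for _ in range(reps):
        sub = np.random.default_rng(int(rng.integers(2**31)))
        outcomes.append(simulate_trial_once(design, gen, sub))
    ok = [o for o in outcomes if not o.failed]
    n_failed = reps - len(ok)
    decisions = np.array([o.decision for o in ok])
    ns = np.array([o.n_at_decision for o in ok], dtype=float)
    denom = max(len(ok), 1)
    return OCReport(
        p_stop_positive=float((decisions == "stop_positive").sum()) / denom,
        p_stop_negative=float((decisions == "stop_negative").sum()) / denom,
        p_max_reached=float(np.isin(decisions, ["max_reached", "continue"]).sum()) / denom,
        n_mean=float(np.mean(ns)) if len(ok) else float("nan"),
        n_median=float(np.median(ns)) if len(ok) else float("nan"),
        n_q25=float(np.quantile(ns, 0.25)) if len(ok) else float("nan"),
        n_q75=float(np.quantile(ns, 0.75)) if len(ok) else float("nan"),
        reps=reps,
        n_failed=n_failed,
        effect=gen.beta_treat,
        valid=n_failed <= 0.1 * reps,
    )


def bf_vs_n_curve(
    design: DesignConfig,
    gen: GeneratorConfig,
    n_grid: list[int],
    reps_per_n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Distribution of the efficacy Bayes factor at fixed sample sizes.

    For each n on the grid, ``reps_per_n`` fixed-n datasets are simulated and
    analysed once; the table reports the median and quartiles of BF_positive.
    Used prospectively to choose the sample size for a new testing round.
    """
    if reps_per_n < 1:
        raise ValueError("reps_per_n must be >= 1")
    if any(n < 4 or n > design.n_max for n in n_grid):
        raise ValueError("grid sample sizes must lie in [4, n_max]")
    rows = []
    for n in n_grid:
        bfs = []
        for _ in range(reps_per_n):
            sub = np.random.default_rng(int(rng.integers(2**31)))
            ds = simulate_completer_stream(gen, design, n, sub)
            data = build_model_data(ds, design.min_observed_days)
            fit = fit_poisson_glmm(
                data, priors=design.priors, rng=sub, method=design.fit_method
            )
            bfs.append(bf_directional(fit, "positive_effect", method=design.bf_method).bf)
        q25, q50, q75 = np.quantile(bfs, [0.25, 0.5, 0.75])
        rows.append({"n": n, "bf_median": q50, "bf_q25": q25, "bf_q75": q75,
                     "reps": reps_per_n})
    return pd.DataFrame(rows)


def effect_from_cohens_d(
    d_target: float,
    gen: GeneratorConfig,
    rng: np.random.Generator,
    n_sim: int = 4000,
    grid: np.ndarray | None = None,
) -> float:
    """Map a planning effect size (Cohen's d on weekly totals) to a log-rate effect.

    The model works on log daily rates but trial planning used a standardised
    mean difference, so the bridge simulates week-4 weekly totals per arm over
    a grid of candidate ``beta_treat`` values, computes the standardised
    difference (delayed - immediate over pooled SD), and interpolates to the
    target d.
    """
    grid = np.linspace(-3.0, 0.0, 25) if grid is None else np.asarray(grid)
    u = rng.normal(0.0, gen.sigma_u, size=n_sim)
    base_log = gen.beta0 + gen.beta_trend + u
    delayed = rng.poisson(7.0 * np.exp(base_log))
    ds = []
    for bt in grid:
        immediate = rng.poisson(7.0 * np.exp(base_log + bt))
        sd_pool = np.sqrt((delayed.var(ddof=1) + immediate.var(ddof=1)) / 2.0)
        ds.append((delayed.mean() - immediate.mean()) / sd_pool)
    ds = np.asarray(ds)
    order = np.argsort(ds)
    return float(np.interp(d_target, ds[order], grid[order]))
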