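"""Descriptive summaries, effect sizes, and diary CSV input/output.

Weekly totals are summarised per arm with medians and interquartile ranges
(linear-interpolation quantile convention) because diary-count outcomes are
skewed with occasional extreme values; means, SDs, percent reduction from
baseline and the zero-week fraction are reported alongside.  Cohen's d is
computed on the raw week-4 weekly totals with a noncentral-t confidence
interval.

The long diary format has one row per participant-phase-day:

    participant_id, enrollment_index, phase, day_index, count, arm[, imputed]

with an *empty* count cell meaning a missing diary day (never zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import nct

from .data import DIARY_DAYS, DailyDiarySeries, ParticipantRecord, TrialDataset


class DiaryParseError(ValueError):
    """Malformed diary CSV row; message names the offending line."""


@dataclass(frozen=True)
class ArmSummary:
    arm: str
    n: int
    median: float
    iqr: tuple[float, float]
    mean: float
    sd: float
    pct_reduction_from_baseline: float
    pct_zero_week4: float


def _week4_totals(records: list[ParticipantRecord]) -> np.ndarray:
    return np.array([r.week4.total() for r in records], dtype=float)


def arm_summaries(ds: TrialDataset, min_observed_days: int = 4) -> dict[str, ArmSummary]:
    """Per-arm week-4 summaries over the analysed population."""
    recs = ds.analysed(min_observed_days)
    out = {}
    for arm in ("immediate", "delayed"):
        sub = [r for r in recs if r.arm == arm]
        if not sub:
            raise ValueError(f"no analysed participants in the {arm} arm")
        totals = _week4_totals(sub)
        base = np.array([r.baseline.total() for r in sub], dtype=float)
        if np.any(base == 0):
            raise ValueError("baseline total of zero should be impossible post-screening")
        reduction = float(np.mean((base - totals) / base) * 100.0)
        q25, q50, q75 = np.quantile(totals, [0.25, 0.5, 0.75])  # linear interpolation
        out[arm] = ArmSummary(
            arm=arm,
            n=len(sub),
            median=float(q50),
            iqr=(float(q25), float(q75)),
            mean=float(totals.mean()),
            sd=float(totals.std(ddof=1)) if len(sub) > 1 else 0.0,
            pct_reduction_from_baseline=reduction,
            pct_zero_week4=float((totals == 0).mean() * 100.0),
        )
    return out


def baseline_summary(ds: TrialDataset, min_observed_days: int = 4) -> dict:
    """Combined-arm baseline weekly-total median and IQR."""
    recs = ds.analysed(min_observed_days)
    totals = np.array([r.baseline.total() for r in recs], dtype=float)
    q25, q50, q75 = np.quantile(totals, [0.25, 0.5, 0.75])
    return {"n": len(recs), "median": float(q50), "iqr": (float(q25), float(q75))}


@dataclass(frozen=True)
class CohensD:
    d: float
    ci_low: float
    ci_high: float
    n_immediate: int
    n_delayed: int


def cohens_d(week4_immediate: np.ndarray, week4_delayed: np.ndarray) -> CohensD:
    """Standardised difference (delayed - immediate) of week-4 weekly totals.

    d = (mean_delayed - mean_immediate) / pooled SD; the 95% CI inverts the
    noncentral-t distribution of the corresponding two-sample t statistic.
    """
    a = np.asarray(week4_immediate, dtype=float)
    b = np.asarray(week4_delayed, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both arms must be non-empty")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df if df > 0 else 0.0
    if sp2 == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    d = (b.mean() - a.mean()) / np.sqrt(sp2)
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_obs = d / scale

    def _cdf(delta: float) -> float:
        v = nct.cdf(t_obs, df, delta)
        if np.isnan(v):   # scipy underflows far in the tails; use the limit
            return 1.0 if delta < t_obs else 0.0
        return float(v)

    def _bound(alpha_tail: float) -> float:
        # noncentrality delta with P(T_df,delta <= t_obs) = alpha_tail
        lo, hi = t_obs - 60 - abs(t_obs), t_obs + 60 + abs(t_obs)
        return brentq(lambda delta: _cdf(delta) - alpha_tail, lo, hi)

    ci_low = _bound(0.975) * scale
    ci_high = _bound(0.025) * scale
    return CohensD(float(d), float(ci_low), float(ci_high), n1, n2)


def cohens_d_from_dataset(ds: TrialDataset, min_observed_days: int = 4) -> CohensD:
    recs = ds.analysed(min_observed_days)
    return cohens_d(
        _week4_totals([r for r in recs if r.arm == "immediate"]),
        _week4_totals([r for r in recs if r.arm == "delayed"]),
    )


# ---------------------------------------------------------------------------
# diary CSV round trip
# ---------------------------------------------------------------------------

_COLUMNS = ["participant_id", "enrollment_index", "phase", "day_index", "count", "arm",
            "imputed"]


def write_diary_csv(ds: TrialDataset, path: str | Path) -> None:
    """Write the long diary format; missing counts become empty cells."""
    rows = []
    for rec in ds:
        for phase, series in (("baseline", rec.baseline), ("week4", rec.week4)):
            if series is None:
                continue
            for day in range(DIARY_DAYS):
                v = series.values[day]
                rows.append({
                    "participant_id": rec.participant_id,
                    "enrollment_index": rec.enrollment_index,
                    "phase": phase,
                    "day_index": day,
                    "count": "" if np.isnan(v) else int(v),
                    "arm": rec.arm or "",
                    "imputed": int(series.imputed[day]),
                })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_diary_csv(path: str | Path) -> TrialDataset:
    """Parse the long diary format back into a dataset.

    Empty count cells are missing days (not zeros); negative or non-integer
    counts raise :class:`DiaryParseError` naming the data line.
    """
    df = pd.read_csv(path, dtype={"count": "object", "arm": "object"})
    missing_cols = {"participant_id", "enrollment_index", "phase", "day_index",
                    "count"} - set(df.columns)
    if missing_cols:
        raise DiaryParseError(f"diary CSV missing columns: {sorted(missing_cols)}")
    if "imputed" not in df.columns:
        df["imputed"] = 0
    if "arm" not in df.columns:
        df["arm"] = ""

    counts = np.full(len(df), np.nan)
    raw = df["count"]
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            continue
        try:
            x = float(v)
        except ValueError:
            raise DiaryParseError(f"line {i + 2}: non-numeric count {v!r}") from None
        if x < 0 or x != round(x):
            raise DiaryParseError(f"line {i + 2}: count must be a non-negative integer, got {v!r}")
        counts[i] = x
    df = df.assign(_count=counts)

    recs = []
    for (pid, eidx), grp in df.groupby(["participant_id", "enrollment_index"], sort=False):
        series = {}
        imputed = {}
        arm = None
        for phase, sub in grp.groupby("phase"):
            sub = sub.sort_values("day_index")
            if list(sub["day_index"]) != list(range(DIARY_DAYS)):
                raise DiaryParseError(
                    f"participant {pid} phase {phase}: day indices must be 0..6"
                )
            series[phase] = DailyDiarySeries(
                phase, sub["_count"].to_numpy(), sub["imputed"].astype(bool).to_numpy()
            )
            arms = {a for a in sub["arm"] if isinstance(a, str) and a}
            if arms:
                arm = arms.pop()
        if "baseline" not in series:
            raise DiaryParseError(f"participant {pid} has no baseline diary")
        recs.append(ParticipantRecord(
            participant_id=str(pid),
            enrollment_index=int(eidx),
            baseline=series["baseline"],
            week4=series.get("week4"),
            arm=arm,
        ))
    recs.sort(key=lambda r: r.enrollment_index)
    return TrialDataset(recs)


# ---------------------------------------------------------------------------
# adverse events and simple plots
# ---------------------------------------------------------------------------

def tally_adverse_events(events: pd.DataFrame) -> pd.DataFrame:
    """Simple per-arm tally of adverse-event records (no clinical adjudication).

    ``events`` needs columns ``arm``, ``participant_id`` and optionally
    ``serious`` (boolean).
    """
    if "serious" not in events.columns:
        events = events.assign(serious=False)
    return events.groupby("arm").agg(
        n_events=("participant_id", "size"),
        n_participants=("participant_id", "nunique"),
        n_serious=("serious", "sum"),
    ).reset_index()


def plot_bf_trace(trace, path: str | Path) -> None:
    """Log-scale plot of the efficacy Bayes factor across looks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trace.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["n"], df["bf_positive"], marker="o")
    ax.axhline(20, color="red", ls="--", lw=1, label="stopping threshold (BF = 20)")
    ax.set_yscale("log")
    ax.set_xlabel("participants with primary outcome")
    ax.set_ylabel("BF for a positive treatment effect")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_arm_boxplots(ds: TrialDataset, path: str | Path, min_observed_days: int = 4) -> None:
    """Baseline and week-4 weekly-total boxplots per arm."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = ds.analysed(min_observed_days)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, phase in zip(axes, ("baseline", "week4")):
        data = [
            [getattr(r, phase if phase == "baseline" else "week4").total()
             for r in recs if r.arm == arm]
            for arm in ("delayed", "immediate")
        ]
        ax.boxplot(data, tick_labels=["delayed", "immediate"])
        ax.set_title(phase)
        ax.set_ylabel("weekly IM total" if phase == "baseline" else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
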