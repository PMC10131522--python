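"""Core data containers for diary-count trial datasets.

A participant keeps a 7-day intrusive-memory (IM) diary twice: once during the
baseline run-in week and once during week 4 (study days 22-28).  Each diary is a
:class:`DailyDiarySeries`; a participant's full trial state (enrollment order,
arm, eligibility, latent generator truth) is a :class:`ParticipantRecord`, and an
ordered collection of those is a :class:`TrialDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

PHASES = ("baseline", "week4")
ARMS = ("immediate", "delayed")
DIARY_DAYS = 7


class DiaryFormatError(ValueError):
    """A diary series does not have the required 7 day slots."""


class IntegrityError(ValueError):
    """Dataset flags are mutually inconsistent (e.g. analysed but never randomised)."""


@dataclass
class DailyDiarySeries:
    """One participant-phase diary: 7 daily counts with explicit missingness.

    ``values`` is a float array of length 7 holding non-negative integer counts,
    with ``nan`` marking a missing diary day.  ``imputed`` flags cells that were
    filled in by the imputation stage (always False for raw data).
    """

    phase: str
    values: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (DIARY_DAYS,):
            raise DiaryFormatError(
                f"diary series must have exactly {DIARY_DAYS} day slots, "
                f"got shape {self.values.shape}"
            )
        if self.phase not in PHASES:
            raise DiaryFormatError(f"unknown phase {self.phase!r}")
        obs = self.values[~np.isnan(self.values)]
        if np.any(obs < 0) or np.any(obs != np.round(obs)):
            raise DiaryFormatError("diary counts must be non-negative integers")
        if self.imputed is None:
            self.imputed = np.zeros(DIARY_DAYS, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
            if self.imputed.shape != (DIARY_DAYS,):
                raise DiaryFormatError("imputed mask must have 7 slots")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def observed_total(self) -> int:
        """Sum of observed counts, missing days contributing 0."""
        return int(np.nansum(self.values))

    def total(self) -> int:
        """Weekly total; requires a complete (post-imputation) series."""
        if not self.is_complete:
            raise IntegrityError("weekly total requested but series has missing days")
        return int(self.values.sum())

    def copy(self) -> "DailyDiarySeries":
        return DailyDiarySeries(self.phase, self.values.copy(), self.imputed.copy())


@dataclass
class ParticipantRecord:
    """Full trial state of one participant.

    ``latents`` carries generator ground truth (random intercept ``u``, true
    daily rates, and the pre-masking counts) and is never consulted by the
    analysis stages; it exists so imputation and CONSORT tests have an oracle.
    """

    participant_id: str
    enrollment_index: int
    baseline: DailyDiarySeries
    week4: Optional[DailyDiarySeries] = None
    arm: Optional[str] = None
    eligible: Optional[bool] = None
    lost_pre_randomisation: bool = False
    completion_index: Optional[int] = None
    latents: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm is not None and self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")

    @property
    def randomised(self) -> bool:
        return self.arm is not None

    def has_outcome(self, min_observed_days: int = 4) -> bool:
        """Primary outcome availability: enough observed week-4 diary days."""
        return self.week4 is not None and self.week4.n_observed >= min_observed_days

    def copy(self) -> "ParticipantRecord":
        return replace(
            self,
            baseline=self.baseline.copy(),
            week4=None if self.week4 is None else self.week4.copy(),
            latents=dict(self.latents),
        )


@dataclass
class TrialDataset:
    """Ordered collection of participants, sorted by enrollment index."""

    participants: list[ParticipantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [p.enrollment_index for p in self.participants]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise IntegrityError("enrollment_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.participants)

    def __getitem__(self, i: int) -> ParticipantRecord:
        return self.participants[i]

    def randomised(self) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.randomised]

    def analysed(self, min_observed_days: int = 4) -> list[ParticipantRecord]:
        out = []
        for p in self.participants:
            if p.has_outcome(min_observed_days):
                if not p.randomised:
                    raise IntegrityError(
                        f"participant {p.participant_id} has outcome data but was "
                        "never randomised"
                    )
                out.append(p)
        return out

    def by_completion_order(self, min_observed_days: int = 4) -> list[ParticipantRecord]:
        """Analysed participants ordered by primary-outcome completion."""
        done = self.analysed(min_observed_days)
        key = lambda p: (
            p.completion_index if p.completion_index is not None else p.enrollment_index
        )
        return sorted(done, key=key)

    def copy(self) -> "TrialDataset":
        return TrialDataset([p.copy() for p in self.participants])
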