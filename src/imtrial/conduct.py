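"""Trial conduct: eligibility screening, minimisation randomisation, CONSORT tallies.

Randomisation is covariate-free minimisation on group size alone: the first
participant (and any tie) is assigned by fair coin; otherwise the smaller arm
receives the new participant with the currently active preferential
probability.  The preferential percentage follows a schedule keyed to the
number already randomised (66% initially, 85% from participant 62 onward in
the default design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AllocationScheduleEntry, DesignConfig
from .data import (
    DIARY_DAYS,
    DailyDiarySeries,
    DiaryFormatError,
    IntegrityError,
    TrialDataset,
)


def screen_eligibility(baseline: DailyDiarySeries, floor: int = 3) -> bool:
    """Eligible iff the observed baseline total reaches the floor.

    Missing diary days contribute 0 to the screen total (a conservative rule:
    unreported days cannot qualify a participant).
    """
    if baseline.values.shape != (DIARY_DAYS,):
        raise DiaryFormatError("baseline series must have 7 day slots")
    return baseline.observed_total() >= floor


@dataclass
class AllocationState:
    """Running state of the minimisation allocator."""

    allocation_pct_schedule: list[AllocationScheduleEntry] = field(
        default_factory=lambda: [
            AllocationScheduleEntry(0, 0.66),
            AllocationScheduleEntry(61, 0.85),
        ]
    )
    n_immediate: int = 0
    n_delayed: int = 0
    next_index: int = 0

    def __post_init__(self) -> None:
        if self.n_immediate < 0 or self.n_delayed < 0:
            raise ValueError("arm counts must be >= 0")
        idx = [e.from_index for e in self.allocation_pct_schedule]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("schedule indices must be strictly increasing")

    def active_p(self) -> float:
        """Preferential probability in force for the next allocation."""
        p = self.allocation_pct_schedule[0].p_preferential
        for entry in self.allocation_pct_schedule:
            if self.next_index >= entry.from_index:
                p = entry.p_preferential
        return p


def allocate_next(state: AllocationState, rng: np.random.Generator) -> tuple[str, AllocationState]:
    """Assign the next participant and return (arm, advanced state)."""
    p = state.active_p()
    if state.n_immediate == state.n_delayed:
        arm = "immediate" if rng.random() < 0.5 else "delayed"
    else:
        smaller = "immediate" if state.n_immediate < state.n_delayed else "delayed"
        larger = "delayed" if smaller == "immediate" else "immediate"
        arm = smaller if rng.random() < p else larger
    new = AllocationState(
        allocation_pct_schedule=state.allocation_pct_schedule,
        n_immediate=state.n_immediate + (arm == "immediate"),
        n_delayed=state.n_delayed + (arm == "delayed"),
        next_index=state.next_index + 1,
    )
    return arm, new


def randomise_stream(
    ds: TrialDataset,
    design: DesignConfig,
    rng: np.random.Generator,
    state: AllocationState | None = None,
) -> tuple[TrialDataset, AllocationState]:
    """Randomise every eligible, retained participant in enrollment order."""
    out = ds.copy()
    if state is None:
        state = AllocationState(allocation_pct_schedule=design.allocation_schedule)
    for rec in out:
        if rec.eligible is None:
            rec.eligible = screen_eligibility(rec.baseline, design.eligibility_floor)
        if rec.eligible and not rec.lost_pre_randomisation:
            rec.arm, state = allocate_next(state, rng)
    return out, state


@dataclass(frozen=True)
class ConsortTally:
    """CONSORT-style accounting of the participant flow."""

    consented: int
    excluded_below_floor: int
    lost_pre_randomisation: int
    randomised_immediate: int
    randomised_delayed: int
    analysed_immediate: int
    analysed_delayed: int

    @property
    def randomised(self) -> int:
        return self.randomised_immediate + self.randomised_delayed

    @property
    def analysed(self) -> int:
        return self.analysed_immediate + self.analysed_delayed

    @property
    def analysed_pct(self) -> float:
        """Analysed as a percentage of randomised."""
        if self.randomised == 0:
            return 0.0
        return 100.0 * self.analysed / self.randomised


def consort_counts(ds: TrialDataset, min_observed_days: int = 4) -> ConsortTally:
    """Tally the participant flow; raises on inconsistent flags."""
    consented = len(ds)
    excluded = sum(1 for p in ds if p.eligible is False)
    lost = sum(1 for p in ds if p.eligible and p.lost_pre_randomisation)
    rand = {"immediate": 0, "delayed": 0}
    analysed = {"immediate": 0, "delayed": 0}
    for p in ds:
        if p.randomised:
            if p.eligible is False:
                raise IntegrityError(
                    f"participant {p.participant_id} randomised despite ineligibility"
                )
            rand[p.arm] += 1
        if p.has_outcome(min_observed_days):
            if not p.randomised:
                raise IntegrityError(
                    f"participant {p.participant_id} analysed but not randomised"
                )
            analysed[p.arm] += 1
    return ConsortTally(
        consented=consented,
        excluded_below_floor=excluded,
        lost_pre_randomisation=lost,
        randomised_immediate=rand["immediate"],
        randomised_delayed=rand["delayed"],
        analysed_immediate=analysed["immediate"],
        analysed_delayed=analysed["delayed"],
    )
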