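"""Constrained daily crossover randomization, blinding labels, and compliance.

Each subject wears the test (imaging-based) fitting on some days and the
control (standard) fitting on others, in a 1:1 ratio over the randomization
period.  To keep exposure balanced during early adaptation, the same fitting
may not be worn more than 2 consecutive days within the first four weeks
(days 1-28) and not more than 4 consecutive days from day 29 onward; a run
straddling the boundary respects each cap on its in-window portion.

Schedules are drawn by constrained sequential sampling: each day a fair coin
chooses among the labels that keep the remainder of the schedule completable
(feasibility is decided exactly by a memoized recursion over
(day, remaining test days, trailing run)).  Every constraint-satisfying
schedule has nonzero probability; the draw is not uniform over the
constrained set and does not need to be.

Blinding: at each fitting visit a fair coin decides which physical processor
(circle or triangle) carries the test program until the next visit.

Compliance is audited as the absolute difference, in percentage points,
between the scheduled and the self-reported share of test-fitting days,
computed over the days the diary actually reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "TEST",
    "CONTROL",
    "WearingSchedule",
    "LabelMap",
    "Diary",
    "generate_schedule",
    "shuffle_labels",
    "compliance_deviation",
]

TEST = "test"
CONTROL = "control"

DEFAULT_PERIOD_DAYS = 84
PHASE_BOUNDARY_DAY = 28  # last day under the stricter cap, inclusive
EARLY_MAX_RUN = 2
LATE_MAX_RUN = 4


@dataclass(frozen=True)
class WearingSchedule:
    """Per-day fitting assignment; day indices run 1..period_length."""

    assignments: tuple[str, ...]
    phase_boundary: int = PHASE_BOUNDARY_DAY
    subject_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", tuple(self.assignments))
        bad = set(self.assignments) - {TEST, CONTROL}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def period_length(self) -> int:
        return len(self.assignments)

    def n_test(self) -> int:
        return sum(a == TEST for a in self.assignments)

    def max_run(self, first_day: int = 1, last_day: int | None = None) -> int:
        """Longest run of identical labels within the day window (inclusive)."""
        last_day = last_day or self.period_length
        window = self.assignments[first_day - 1 : last_day]
        best = run = 0
        prev = None
        for a in window:
            run = run + 1 if a == prev else 1
            prev = a
            best = max(best, run)
        return best


@dataclass(frozen=True)
class LabelMap:
    """Per-visit mapping of fitting -> processor label, fixed until next visit."""

    visit_days: tuple[int, ...]
    test_label: tuple[str, ...]  # "circle" or "triangle" per visit

    def label_for(self, day: int, fitting: str) -> str:
        pos = int(np.searchsorted(self.visit_days, day, side="right")) - 1
        if pos < 0:
            raise ValueError(f"day {day} precedes the first visit")
        test = self.test_label[pos]
        other = "triangle" if test == "circle" else "circle"
        return test if fitting == TEST else other


@dataclass(frozen=True)
class Diary:
    """Self-reported wearing per day; None marks a day with no report."""

    worn: tuple[str | None, ...]
    subject_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "worn", tuple(self.worn))


def _cap(day: int, phase_boundary: int) -> int:
    return EARLY_MAX_RUN if day <= phase_boundary else LATE_MAX_RUN


@lru_cache(maxsize=None)
def _feasible(
    period: int, boundary: int, day: int, test_left: int, ctrl_left: int,
    last: str | None, run: int,
) -> bool:
    """Can days ``day..period`` be filled given the trailing in-window run?

    ``run`` counts only the trailing days of the current run that fall inside
    the active cap window (it resets when crossing the phase boundary, since
    the late cap applies to the in-window portion of a straddling run).
    """
    if day > period:
        return abs(test_left - ctrl_left) <= 1 and test_left >= 0 and ctrl_left >= 0
    for label, left in ((TEST, test_left), (CONTROL, ctrl_left)):
        if left == 0:
            continue
        new_run = run + 1 if label == last else 1
        if new_run > _cap(day, boundary):
            continue
        nxt_run = 0 if day == boundary else new_run  # window resets after boundary
        nt = test_left - (label == TEST)
        nc = ctrl_left - (label == CONTROL)
        if _feasible(period, boundary, day + 1, nt, nc, label, nxt_run):
            return True
    return False


def generate_schedule(
    period_length: int = DEFAULT_PERIOD_DAYS,
    seed: int | np.random.Generator | None = None,
    phase_boundary: int = PHASE_BOUNDARY_DAY,
    subject_id: str = "",
) -> WearingSchedule:
    """Draw a wearing schedule satisfying the ratio and run-length constraints.

    The 1:1 ratio is enforced overall: even lengths split exactly in half,
    odd lengths differ by one day with the surplus arm chosen at random.
    """
    if period_length < 1:
        raise ValueError("period_length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    test_left = period_length // 2
    ctrl_left = period_length - test_left
    if period_length % 2 and rng.random() < 0.5:
        test_left, ctrl_left = ctrl_left, test_left

    assignments: list[str] = []
    last: str | None = None
    run = 0
    for day in range(1, period_length + 1):
        options = []
        for label in (TEST, CONTROL):
            left = test_left if label == TEST else ctrl_left
            if left == 0:
                continue
            new_run = run + 1 if label == last else 1
            if new_run > _cap(day, phase_boundary):
                continue
            nxt_run = 0 if day == phase_boundary else new_run
            nt = test_left - (label == TEST)
            nc = ctrl_left - (label == CONTROL)
            if _feasible(period_length, phase_boundary, day + 1, nt, nc, label, nxt_run):
                options.append(label)
        if not options:  # cannot happen for caps >= 2, guarded anyway
            raise RuntimeError(f"no feasible label on day {day}")
        label = options[rng.integers(len(options))] if len(options) > 1 else options[0]
        new_run = run + 1 if label == last else 1
        run = 0 if day == phase_boundary else new_run
        last = label
        if label == TEST:
            test_left -= 1
        else:
            ctrl_left -= 1
        assignments.append(label)
    return WearingSchedule(tuple(assignments), phase_boundary, subject_id=subject_id)


def shuffle_labels(
    visit_days, seed: int | np.random.Generator | None = None
) -> LabelMap:
    """Fair-coin fitting<->processor-label assignment at each fitting visit."""
    days = tuple(int(d) for d in visit_days)
    if list(days) != sorted(days):
        raise ValueError("visit days must be sorted")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = tuple("circle" if rng.random() < 0.5 else "triangle" for _ in days)
    return LabelMap(visit_days=days, test_label=labels)


def compliance_deviation(schedule: WearingSchedule, diary: Diary) -> float:
    """Deviation (%) between intended and actual wearing of the test fitting.

    Over the days the diary reports, the intended test-fitting share is
    compared with the share of days on which the test fitting was worn as
    scheduled; the difference is the fraction of scheduled test days on which
    the diary reports the other fitting, x 100.  A perfectly followed
    schedule gives 0%; a diary reporting the control fitting on every
    scheduled test day gives 50% on a balanced schedule.  Days without a
    report are dropped from both shares.
    """
    if len(diary.worn) != schedule.period_length:
        raise ValueError(
            f"diary covers {len(diary.worn)} days, schedule {schedule.period_length}"
        )
    pairs = [
        (intended, worn)
        for intended, worn in zip(schedule.assignments, diary.worn)
        if worn is not None
    ]
    if not pairs:
        raise ValueError("diary reports no days")
    n = len(pairs)
    intended_share = sum(a == TEST for a, _ in pairs) / n
    followed_share = sum(a == TEST and w == TEST for a, w in pairs) / n
    return abs(intended_share - followed_share) * 100.0
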