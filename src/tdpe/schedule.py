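"""Probabilistic taste-conditioning trial schedule.

Three visual conditioned stimuli (CS) predict three taste outcomes (US):
sucrose solution, no solution, and a neutral artificial-saliva control.
The sucrose and no-solution contingencies are probabilistic: a fixed
fraction of sucrose-CS trials delivers no solution (unexpected omission,
negative prediction error) and the same fraction of no-solution-CS trials
delivers sucrose (unexpected receipt, positive prediction error).  The
saliva pairing is deterministic.  A fixed congruent sucrose block at the
start of the run establishes the CS-US association before any violation
can occur.

Violation counts are enforced exactly (a design ratio, not a binomial
draw), so delivered-US marginal counts always equal the configured trial
counts.  Trials are presented at a constant onset-to-onset spacing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CS",
    "US",
    "Condition",
    "Trial",
    "Schedule",
    "ScheduleSummary",
    "generate_schedule",
    "schedule_summary",
    "write_events_tsv",
    "read_events_tsv",
]


class CS(str, enum.Enum):
    """Conditioned (visual) stimulus identity."""

    SUCROSE_CS = "SUCROSE_CS"
    NOSOL_CS = "NOSOL_CS"
    SALIVA_CS = "SALIVA_CS"


class US(str, enum.Enum):
    """Unconditioned (taste) stimulus identity."""

    SUCROSE = "SUCROSE"
    NO_SOLUTION = "NO_SOLUTION"
    SALIVA = "SALIVA"


#: Congruent CS -> US pairings.
CONGRUENT: dict[CS, US] = {
    CS.SUCROSE_CS: US.SUCROSE,
    CS.NOSOL_CS: US.NO_SOLUTION,
    CS.SALIVA_CS: US.SALIVA,
}


@dataclass(frozen=True)
class Condition:
    """A CS-US pairing for one trial."""

    cs: CS
    us: US

    def __post_init__(self) -> None:
        if self.cs is CS.SALIVA_CS and self.us is not US.SALIVA:
            raise ValueError("saliva CS is always paired with saliva US")

    @property
    def is_violation(self) -> bool:
        """True iff the US is incongruent with the CS (sucrose/no-solution swap)."""
        return (self.cs is CS.SUCROSE_CS and self.us is US.NO_SOLUTION) or (
            self.cs is CS.NOSOL_CS and self.us is US.SUCROSE
        )


@dataclass(frozen=True)
class Trial:
    """One trial: 1-based index, pairing, onset in seconds from run start."""

    index: int
    condition: Condition
    onset_s: float
    is_fixed_initial: bool = False

    @property
    def is_violation(self) -> bool:
        return self.condition.is_violation


@dataclass(frozen=True)
class Schedule:
    """Ordered trial sequence with constant onset-to-onset spacing."""

    trials: tuple[Trial, ...]
    trial_soa_s: float
    seed: int | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterable[Trial]:
        return iter(self.trials)

    @property
    def duration_s(self) -> float:
        return len(self.trials) * self.trial_soa_s

    def us_onsets_s(self, us_delay_s: float = 2.0) -> np.ndarray:
        """US delivery times: CS onset plus the CS presentation duration."""
        return np.array([t.onset_s + us_delay_s for t in self.trials])


@dataclass(frozen=True)
class ScheduleSummary:
    n_trials: int
    us_counts: dict[US, int]
    cs_counts: dict[CS, int]
    n_positive_pe: int  # no-solution CS followed by sucrose
    n_negative_pe: int  # sucrose CS followed by no solution
    n_fixed_initial: int
    total_duration_min: float


def generate_schedule(
    n_sucrose: int = 100,
    n_nosol: int = 100,
    n_saliva: int = 80,
    p_violation: float = 0.2,
    n_fixed_initial: int = 10,
    trial_soa_s: float = 6.0,
    seed: int = 0,
    violations_from_all: bool = False,
) -> Schedule:
    """Generate the conditioning schedule with exact violation counts.

    Parameters
    ----------
    n_sucrose, n_nosol, n_saliva
        Trials per CS identity (the delivered-US marginals match these
        exactly because violations swap outcomes pairwise between the
        sucrose and no-solution conditions).
    p_violation
        Fraction of sucrose-CS trials delivering no solution, and of
        no-solution-CS trials delivering sucrose; enforced as an exact
        count ``round(p_violation * n)``.
    n_fixed_initial
        Leading block of congruent sucrose trials in fixed order.
    violations_from_all
        If True, the sucrose-CS violation count is ``round(p * n_sucrose)``
        even though violations can only occupy the non-fixed trials (the
        default).  Retained as a switch for the alternative reading where
        the fraction applies to the non-fixed trials only, giving
        ``round(p * (n_sucrose - n_fixed_initial))``.
    """
    if not 0.0 <= p_violation <= 1.0:
        raise ValueError("p_violation must lie in [0, 1]")
    if min(n_sucrose, n_nosol, n_saliva) < 0:
        raise ValueError("trial counts must be non-negative")
    if n_fixed_initial > n_sucrose:
        raise ValueError("n_fixed_initial cannot exceed n_sucrose")

    n_free_sucrose = n_sucrose - n_fixed_initial
    base = n_free_sucrose if violations_from_all else n_sucrose
    n_viol_suc = round(p_violation * base)
    n_viol_nosol = round(p_violation * n_nosol)
    if n_viol_suc > n_free_sucrose:
        raise ValueError(
            f"{n_viol_suc} sucrose-CS violations do not fit in "
            f"{n_free_sucrose} non-fixed sucrose trials"
        )

    conditions: list[Condition] = []
    conditions += [Condition(CS.SUCROSE_CS, US.NO_SOLUTION)] * n_viol_suc
    conditions += [Condition(CS.SUCROSE_CS, US.SUCROSE)] * (n_free_sucrose - n_viol_suc)
    conditions += [Condition(CS.NOSOL_CS, US.SUCROSE)] * n_viol_nosol
    conditions += [Condition(CS.NOSOL_CS, US.NO_SOLUTION)] * (n_nosol - n_viol_nosol)
    conditions += [Condition(CS.SALIVA_CS, US.SALIVA)] * n_saliva

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))
    shuffled = [conditions[i] for i in order]

    trials: list[Trial] = []
    for i in range(n_fixed_initial):
        trials.append(
            Trial(i + 1, Condition(CS.SUCROSE_CS, US.SUCROSE), i * trial_soa_s, True)
        )
    for j, cond in enumerate(shuffled):
        idx = n_fixed_initial + j
        trials.append(Trial(idx + 1, cond, idx * trial_soa_s, False))
    return Schedule(tuple(trials), trial_soa_s, seed)


def schedule_summary(sched: Schedule) -> ScheduleSummary:
    """Count trials per condition and report the total task duration."""
    if not sched.trials:
        raise ValueError("schedule is empty")
    us_counts = {u: 0 for u in US}
    cs_counts = {c: 0 for c in CS}
    n_pos = n_neg = n_fixed = 0
    for t in sched:
        us_counts[t.condition.us] += 1
        cs_counts[t.condition.cs] += 1
        if t.condition.cs is CS.NOSOL_CS and t.condition.us is US.SUCROSE:
            n_pos += 1
        if t.condition.cs is CS.SUCROSE_CS and t.condition.us is US.NO_SOLUTION:
            n_neg += 1
        if t.is_fixed_initial:
            n_fixed += 1
    return ScheduleSummary(
        n_trials=len(sched),
        us_counts=us_counts,
        cs_counts=cs_counts,
        n_positive_pe=n_pos,
        n_negative_pe=n_neg,
        n_fixed_initial=n_fixed,
        total_duration_min=len(sched) * sched.trial_soa_s / 60.0,
    )


def to_frame(sched: Schedule, cs_duration_s: float = 2.0) -> pd.DataFrame:
    """Schedule as a BIDS-style events table."""
    rows = []
    for t in sched:
        rows.append(
            {
                "onset": round(t.onset_s, 3),
                "duration": cs_duration_s,
                "trial_type": "violation" if t.is_violation else "congruent",
                "cs": t.condition.cs.value,
                "us": t.condition.us.value,
                "is_violation": int(t.is_violation),
            }
        )
    cols = ["onset", "duration", "trial_type", "cs", "us", "is_violation"]
    return pd.DataFrame(rows, columns=cols)


def write_events_tsv(sched: Schedule, path: str | Path) -> None:
    """Write the schedule as a tab-separated BIDS-style events file."""
    to_frame(sched).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events_tsv(path: str | Path, n_fixed_initial: int = 10) -> Schedule:
    """Read a schedule back from an events file.

    The events format does not carry the generating seed, so the returned
    schedule has ``seed=None`` (seed is excluded from equality).  The first
    ``n_fixed_initial`` trials are marked as the fixed congruent block.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: no trials")
    onsets = df["onset"].to_numpy(float)
    soa = float(onsets[1] - onsets[0]) if len(df) > 1 else 6.0
    trials = tuple(
        Trial(
            i + 1,
            Condition(CS(row.cs), US(row.us)),
            float(row.onset),
            i < n_fixed_initial,
        )
        for i, row in enumerate(df.itertuples())
    )
    return Schedule(trials, soa, None)
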