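"""Automation-correctness schedules for the three reliability-learning experiments.

Participants classified "contacts" (vessels) with the help of an automated
decision aid whose accuracy followed a pre-set design: each *trial* (a block of
8 or 10 contacts) contained a fixed number of automation-correct outcomes, and
the per-trial counts stepped between phases of differing true reliability.
Eight between-subjects conditions exist across three experiments:

* Experiment 1 (15 trials x 8 contacts): ``high`` starts at 90% reliability
  (one 8/8 trial, four 7/8 trials), ``low`` at 60% (one 4/8, four 5/8); both
  continue at 75% (6/8) for trials 6-15.
* Experiment 2 (16 trials x 10 contacts): ``constant`` is 75% throughout
  (7/10 for half the trials, 8/10 for the other half); ``start_high`` and
  ``start_low`` alternate 95% (two 10/10 + two 9/10) and 55% (two 5/10 + two
  6/10) phases of four trials, in opposite orders.
* Experiment 3 (16 trials x 10 contacts): 90% (9/10) for trials 1-4 and 9-16,
  with a drop to 30% / 50% / 70% (3, 5, or 7 of 10) in trials 5-8 for the
  ``large_drop`` / ``medium_drop`` / ``small_drop`` conditions.

The designs fix only the per-trial correct counts; the order of correct and
incorrect outcomes within a trial, and which trial within a phase carries an
off count (e.g. the single 8/8 trial), are realized by a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EXPERIMENT_CONDITIONS: dict[int, tuple[str, ...]] = {
    1: ("high", "low"),
    2: ("start_high", "start_low", "constant"),
    3: ("large_drop", "medium_drop", "small_drop"),
}

ALL_CONDITIONS: tuple[tuple[int, str], ...] = tuple(
    (exp, cond) for exp, conds in EXPERIMENT_CONDITIONS.items() for cond in conds
)


@dataclass(frozen=True)
class Phase:
    """A run of trials sharing one true reliability level.

    ``counts`` lists the automation-correct count of every trial in the phase
    (a multiset; assignment of counts to trial positions is randomized when
    the schedule is realized).
    """

    counts: tuple[int, ...]
    contacts_per_trial: int

    @property
    def n_trials(self) -> int:
        return len(self.counts)

    @property
    def true_reliability(self) -> float:
        return sum(self.counts) / (self.n_trials * self.contacts_per_trial)


@dataclass(frozen=True)
class PhasePlan:
    """Per-condition design: ordered phases of per-trial correct counts."""

    experiment: int
    condition: str
    phases: tuple[Phase, ...]

    @property
    def contacts_per_trial(self) -> int:
        return self.phases[0].contacts_per_trial

    @property
    def n_trials(self) -> int:
        return sum(ph.n_trials for ph in self.phases)

    @property
    def n_contacts(self) -> int:
        return self.n_trials * self.contacts_per_trial

    def trial_reliabilities(self) -> np.ndarray:
        """Phase (stairstep) reliability for each trial, in trial order."""
        out = []
        for ph in self.phases:
            out.extend([ph.true_reliability] * ph.n_trials)
        return np.asarray(out)


@dataclass(frozen=True)
class AutomationSchedule:
    """A realized sequence of automation-correct bits, grouped into trials."""

    experiment: int
    condition: str
    trials: tuple[tuple[int, ...], ...]
    seed: int

    def flatten(self) -> np.ndarray:
        return flatten(self)

    @property
    def n_contacts(self) -> int:
        return sum(len(t) for t in self.trials)

    def trial_index(self) -> np.ndarray:
        """1-based trial index aligned to the flattened bit sequence."""
        return np.repeat(
            np.arange(1, len(self.trials) + 1), [len(t) for t in self.trials]
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per contact: experiment, condition, trial and contact index, bit."""
        bits = self.flatten()
        return pd.DataFrame(
            {
                "experiment": self.experiment,
                "condition": self.condition,
                "trial_index": self.trial_index(),
                "contact_index": np.arange(1, bits.size + 1),
                "automation_correct": bits,
            }
        )


def build_phase_plan(experiment: int, condition: str) -> PhasePlan:
    """Return the per-trial correct-count design for one experimental condition."""
    key = (experiment, condition)
    if key == (1, "high"):
        phases = (Phase((8, 7, 7, 7, 7), 8), Phase((6,) * 10, 8))
    elif key == (1, "low"):
        phases = (Phase((4, 5, 5, 5, 5), 8), Phase((6,) * 10, 8))
    elif key == (2, "constant"):
        phases = (Phase((7,) * 8 + (8,) * 8, 10),)
    elif key in ((2, "start_high"), (2, "start_low")):
        high = Phase((10, 10, 9, 9), 10)
        low = Phase((5, 5, 6, 6), 10)
        order = (high, low, high, low) if condition == "start_high" else (low, high, low, high)
        phases = order
    elif key in ((3, "large_drop"), (3, "medium_drop"), (3, "small_drop")):
        drop = {"large_drop": 3, "medium_drop": 5, "small_drop": 7}[condition]
        phases = (Phase((9,) * 4, 10), Phase((drop,) * 4, 10), Phase((9,) * 8, 10))
    else:
        raise ValueError(
            f"unknown (experiment, condition) pair: ({experiment!r}, {condition!r}); "
            f"valid pairs are {ALL_CONDITIONS}"
        )
    return PhasePlan(experiment, condition, phases)


def realize_schedule(plan: PhasePlan, seed: int) -> AutomationSchedule:
    """Realize a plan into a concrete bit schedule.

    Within each phase the multiset of per-trial correct counts is assigned to
    trial positions by a seeded permutation, and within each trial the correct
    and incorrect outcomes are uniformly shuffled. Deterministic for a fixed
    seed; the total number of correct contacts is invariant to the seed.
    """
    rng = np.random.default_rng(seed)
    trials: list[tuple[int, ...]] = []
    for ph in plan.phases:
        counts = rng.permutation(np.asarray(ph.counts))
        for count in counts:
            trial = np.zeros(ph.contacts_per_trial, dtype=int)
            trial[: int(count)] = 1
            trials.append(tuple(int(b) for b in rng.permutation(trial)))
    return AutomationSchedule(plan.experiment, plan.condition, tuple(trials), seed)


def make_schedule(experiment: int, condition: str, seed: int) -> AutomationSchedule:
    """Convenience: ``realize_schedule(build_phase_plan(...), seed)``."""
    return realize_schedule(build_phase_plan(experiment, condition), seed)


def flatten(schedule: AutomationSchedule) -> np.ndarray:
    """Concatenate trials in order into the contact-level bit sequence."""
    if not schedule.trials:
        return np.zeros(0, dtype=int)
    return np.concatenate([np.asarray(t, dtype=int) for t in schedule.trials])
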