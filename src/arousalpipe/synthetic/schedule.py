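"""Session schedules: block orders, phase timings and event trains.

Trial timing convention: every trial starts at t=0 with the instruction
phase; phase onsets are trial-relative.  Event onsets (TMS pulses, oddball
tones) are stored relative to *modulation onset*, matching how the analysis
windows are specified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (CohortConfig, EXPERIMENT_CONDITIONS, PHASE_DURATIONS,
                     TRIALS_PER_CONDITION)

PHASE_ORDER = ("instruction", "baseline", "modulation", "feedback", "break")

#: oddball geometry: tones per trial, inter-tone onset interval bounds (s),
#: and the minimum number of standards between two targets
TONES_PER_TRIAL = 8
ISI_RANGE = (1.8, 2.2)
MIN_STANDARDS_BETWEEN_TARGETS = 2


@dataclass(frozen=True)
class Event:
    label: str            # tms_pulse | tone_standard | tone_target
    onset_s: float        # relative to modulation onset


@dataclass(frozen=True)
class Trial:
    trial_id: int
    condition: str
    block_index: int
    phases: dict[str, tuple[float, float]]  # name -> (onset_s, duration_s)
    events: tuple[Event, ...] = ()

    @property
    def modulation_onset(self) -> float:
        return self.phases["modulation"][0]

    @property
    def duration(self) -> float:
        on, dur = self.phases["break"]
        return on + dur


@dataclass(frozen=True)
class SessionSchedule:
    experiment: str
    participant: int
    trials: tuple[Trial, ...]

    def by_condition(self, condition: str) -> list[Trial]:
        return [t for t in self.trials if t.condition == condition]


def _block_order(conditions: tuple[str, ...], n_blocks: int,
                 participant: int, cohort_seed: int) -> list[str]:
    """Seeded Latin-square counterbalancing of condition block order.

    A cyclic Latin square over a cohort-level seeded base permutation of
    the conditions; participants walk through its rows.
    """
    k = len(conditions)
    base = list(np.random.default_rng([cohort_seed, 0, 1])
                .permutation(conditions))
    row = participant % k
    order = base[row:] + base[:row]
    reps = n_blocks // k
    return [c for _ in range(reps) for c in order]


def generate_oddball_sequence(n_trials: int, rng: np.random.Generator
                              ) -> list[list[Event]]:
    """Tone event lists for ``n_trials`` oddball trials.

    Each trial carries 8 tones with onset gaps uniform in [1.8, 2.2] s (the
    first tone 1.8-2.2 s after modulation onset), the first tone always a
    standard, one or two targets per trial, and at least two standards
    between consecutive targets.  Over a full 117-trial session this yields
    exactly 186 targets and 750 standards (69 two-target and 48 one-target
    trials); other trial counts use the same 69/117 proportion.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_two = int(round(n_trials * 69 / 117))
    kinds = np.array([2] * n_two + [1] * (n_trials - n_two))
    rng.shuffle(kinds)

    # admissible target slot patterns (slot 0 is always a standard)
    single = [(i,) for i in range(1, TONES_PER_TRIAL)]
    gap = MIN_STANDARDS_BETWEEN_TARGETS + 1
    double = [(i, j) for i in range(1, TONES_PER_TRIAL)
              for j in range(i + gap, TONES_PER_TRIAL)]

    trials: list[list[Event]] = []
    for k in kinds:
        slots = single[rng.integers(len(single))] if k == 1 else \
            double[rng.integers(len(double))]
        onsets = np.cumsum(rng.uniform(*ISI_RANGE, size=TONES_PER_TRIAL))
        events = [Event("tone_target" if i in slots else "tone_standard",
                        float(onsets[i])) for i in range(TONES_PER_TRIAL)]
        trials.append(events)
    return trials


def generate_schedule(config: CohortConfig, participant: int) -> SessionSchedule:
    """Build one participant's full session schedule.

    Counterbalancing, pulse jitter and tone sequences are all drawn from a
    generator keyed on (cohort seed, participant), so the same config and
    seed always produce the identical schedule.
    """
    if config.experiment not in EXPERIMENT_CONDITIONS:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    rng = np.random.default_rng([config.seed, participant, 1])
    exp = config.experiment
    conds = EXPERIMENT_CONDITIONS[exp]
    durations = PHASE_DURATIONS[exp]
    per_cond = TRIALS_PER_CONDITION[exp]
    trials_per_block = 10 if exp in ("exp1", "exp2") else 13
    n_blocks = per_cond * len(conds) // trials_per_block
    order = _block_order(conds, n_blocks, participant, config.seed)

    phases: dict[str, tuple[float, float]] = {}
    onset = 0.0
    for name in PHASE_ORDER:
        phases[name] = (onset, durations[name])
        onset += durations[name]

    n_trials = per_cond * len(conds)
    oddball = generate_oddball_sequence(n_trials, rng) if exp == "exp3" else None

    trials: list[Trial] = []
    tid = 0
    for block, cond in enumerate(order):
        for _ in range(trials_per_block):
            if exp == "exp1":
                events: tuple[Event, ...] = (
                    Event("tms_pulse", float(rng.uniform(3.0, 4.0))),
                    Event("tms_pulse", 11.0),
                )
            elif exp == "exp3":
                events = tuple(oddball[tid])
            else:
                events = ()
            trials.append(Trial(tid, cond, block, dict(phases), events))
            tid += 1
    return SessionSchedule(exp, participant, tuple(trials))


def min_target_gap(trials: list[list[Event]]) -> float:
    """Smallest onset-to-onset separation of consecutive targets per trial."""
    best = np.inf
    for events in trials:
        onsets = [e.onset_s for e in events if e.label == "tone_target"]
        for a, b in zip(onsets, onsets[1:]):
            best = min(best, b - a)
    return float(best)
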