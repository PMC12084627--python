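"""Participant-level assembly of schedules, truths, and signals."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ..montage import Montage, load_montage
from .config import CohortConfig, ParticipantTruth, generate_truth
from .schedule import SessionSchedule, generate_schedule
from .signals import (EegTrial, EmgTrial, PupilRaw, simulate_eeg_trial,
                      simulate_emg_trial, simulate_pupil_trial,
                      simulate_rr_series)


def _trial_rng(config: CohortConfig, participant: int, trial_id: int,
               stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, participant, trial_id, stream])


@dataclass
class ParticipantData:
    """All generated data for one synthetic participant."""

    participant: int
    config: CohortConfig
    truth: ParticipantTruth
    schedule: SessionSchedule
    montage: Montage | None = None
    pupil: dict[int, PupilRaw] | None = None        # trial_id -> trace
    eeg: dict[int, EegTrial] | None = None
    rr: dict[int, np.ndarray] | None = None         # trial_id -> peak times
    emg: dict[int, EmgTrial] | None = None


def generate_participant(config: CohortConfig, participant: int,
                         montage: Montage | None = None,
                         with_pupil: bool | None = None,
                         with_eeg: bool | None = None,
                         with_rr: bool | None = None,
                         with_emg: bool | None = None,
                         eeg_erp_windows_only: bool = False) -> ParticipantData:
    """Generate one participant's session.

    Modality defaults follow the experiment: exp1 records pupil + EMG +
    R-peaks, exp2 pupil + EEG + R-peaks, exp3 EEG (tones) only.  Everything
    is a deterministic function of (config, seed, participant).
    """
    exp = config.experiment
    if with_pupil is None:
        with_pupil = exp in ("exp1", "exp2")
    if with_eeg is None:
        with_eeg = exp in ("exp2", "exp3")
    if with_rr is None:
        with_rr = exp in ("exp1", "exp2")
    if with_emg is None:
        with_emg = exp == "exp1"
    if with_eeg and montage is None:
        montage = load_montage(config.n_channels)

    truth = generate_truth(config, participant)
    schedule = generate_schedule(config, participant)
    data = ParticipantData(participant, config, truth, schedule, montage)
    if with_pupil:
        data.pupil = {t.trial_id: simulate_pupil_trial(
            t, truth, config, _trial_rng(config, participant, t.trial_id, 2))
            for t in schedule.trials}
    if with_eeg:
        data.eeg = {t.trial_id: simulate_eeg_trial(
            t, truth, config, montage,
            _trial_rng(config, participant, t.trial_id, 3),
            erp_windows_only=eeg_erp_windows_only)
            for t in schedule.trials}
    if with_rr:
        data.rr = {t.trial_id: simulate_rr_series(
            t, truth, config, _trial_rng(config, participant, t.trial_id, 4))
            for t in schedule.trials}
    if with_emg:
        data.emg = {t.trial_id: simulate_emg_trial(
            t, truth, config, _trial_rng(config, participant, t.trial_id, 5))
            for t in schedule.trials}
    return data


def iter_participants(config: CohortConfig, **kwargs
                      ) -> Iterator[ParticipantData]:
    montage = kwargs.pop("montage", None)
    if montage is None and config.experiment in ("exp2", "exp3"):
        montage = load_montage(config.n_channels)
    for p in range(config.n_participants):
        yield generate_participant(config, p, montage=montage, **kwargs)
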