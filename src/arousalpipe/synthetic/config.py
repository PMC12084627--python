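"""Cohort configuration and per-participant ground truth.

The generator emulates the three biofeedback experiments:

* **exp1** -- 20 trials x {up, down, rest}, two TMS pulses per trial
  (first jittered 3-4 s, second at 11 s after modulation onset), pupil +
  EMG + R-peak streams.
* **exp2** -- 30 up + 30 down trials, 15 s modulation, pupil + EEG +
  R-peak streams.
* **exp3** -- 9 blocks x 13 trials of {up, down, control} with an embedded
  auditory oddball (8 tones per trial, 186 targets / 750 standards per
  session), EEG stream with tone-locked ERPs.

Condition effects are parameterized per condition and coupled across
measures through a per-participant latent arousal factor, so that a
participant who self-regulates pupil size well also shows a larger
spectral-exponent difference (the cross-measure correlation the analysis
stage is meant to recover).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

EXPERIMENT_CONDITIONS: dict[str, tuple[str, ...]] = {
    "exp1": ("up", "down", "rest"),
    "exp2": ("up", "down"),
    "exp3": ("up", "down", "control"),
}

#: trials per condition for each experiment
TRIALS_PER_CONDITION = {"exp1": 20, "exp2": 30, "exp3": 39}

#: per-trial phase durations in seconds (instruction, baseline, modulation,
#: feedback, break)
PHASE_DURATIONS = {
    "exp1": {"instruction": 1.0, "baseline": 4.0, "modulation": 15.0,
             "feedback": 2.0, "break": 2.0},
    "exp2": {"instruction": 2.0, "baseline": 3.0, "modulation": 15.0,
             "feedback": 2.0, "break": 2.0},
    "exp3": {"instruction": 1.0, "baseline": 4.0, "modulation": 18.0,
             "feedback": 2.0, "break": 2.0},
}


def _default_deltas(experiment: str, up: float, down: float) -> dict[str, float]:
    out = {"up": up, "down": down}
    for c in EXPERIMENT_CONDITIONS[experiment]:
        out.setdefault(c, 0.0)
    return out


@dataclass
class CohortConfig:
    """Seeded description of a synthetic cohort.

    Effect-size dictionaries map condition labels to the *population* value
    of the measure (or measure delta) for that condition; per-participant
    values scatter around these via the latent arousal factor plus
    independent between-subject noise.
    """

    experiment: str = "exp2"
    n_participants: int = 12
    seed: int = 0

    # --- condition effects (population level) ---------------------------
    #: baseline-corrected pupil plateau change, mm
    pupil_delta_mm: Mapping[str, float] | None = None
    #: aperiodic exponent chi (positive; larger = steeper spectrum)
    exponent: Mapping[str, float] | None = None
    #: mean heart rate, bpm
    hr_bpm: Mapping[str, float] | None = None
    #: RMSSD, ms
    rmssd_ms: Mapping[str, float] | None = None
    #: MEP peak-to-peak, mV (exp1)
    mep_mv: Mapping[str, float] | None = None
    #: target-evoked P300 amplitude, uV (exp3)
    p300_uv: Mapping[str, float] | None = None
    #: early negative component amplitude, uV, condition-invariant
    n100_uv: float = -3.0
    #: late positivity evoked by standard tones, uV, condition-invariant
    standard_p300_uv: float = 1.0

    # --- latent coupling and between-subject scatter --------------------
    latent_arousal_sd: float = 0.4
    pupil_between_sd_mm: float = 0.115
    exponent_between_sd: float = 0.07
    hr_between_sd_bpm: float = 1.2
    rmssd_between_sd_ms: float = 2.0
    mep_between_sd: float = 0.08      # multiplicative, relative to rest
    p300_between_sd_uv: float = 0.8

    # --- noise ----------------------------------------------------------
    pupil_noise_sd_mm: float = 0.05
    eeg_noise_scale: float = 1.0      # multiplies the 1/f amplitude
    rr_jitter_sd_ms: float = 10.0
    bgemg_rms_mv: float = 0.005
    blink_rate_hz: float = 0.12
    spike_rate_hz: float = 0.04
    #: target fraction of 3-s bins overlapping an artifact burst
    artifact_fraction: float = 0.1
    p_miss: float = 0.05
    p_false_alarm: float = 0.01

    # --- acquisition ----------------------------------------------------
    n_channels: int = 64
    eeg_fs_hz: float = 250.0
    pupil_fs_hz: float = 60.0
    emg_fs_hz: float = 5000.0
    mep_trial_cv: float = 0.2         # lognormal sigma of per-trial MEPs
    alpha_peak_height: float = 0.6    # log10 power height of the 10 Hz bump

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_CONDITIONS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("latent_arousal_sd", "pupil_noise_sd_mm", "eeg_noise_scale",
                     "rr_jitter_sd_ms", "bgemg_rms_mv", "blink_rate_hz",
                     "spike_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        exp = self.experiment
        if self.pupil_delta_mm is None:
            self.pupil_delta_mm = _default_deltas(exp, 0.25, -0.25)
        if self.exponent is None:
            self.exponent = _default_deltas(exp, 1.85, 2.15)
            self.exponent = {c: (v if v else 2.0) for c, v in self.exponent.items()}
        if self.hr_bpm is None:
            self.hr_bpm = {c: {"up": 71.5, "down": 68.5}.get(c, 70.0)
                           for c in EXPERIMENT_CONDITIONS[exp]}
        if self.rmssd_ms is None:
            self.rmssd_ms = {c: {"up": 37.5, "down": 42.5}.get(c, 40.0)
                             for c in EXPERIMENT_CONDITIONS[exp]}
        if self.mep_mv is None:
            self.mep_mv = {c: {"up": 1.15, "down": 0.85}.get(c, 1.0)
                           for c in EXPERIMENT_CONDITIONS[exp]}
        if self.p300_uv is None:
            self.p300_uv = {c: {"down": 7.0}.get(c, 5.0)
                            for c in EXPERIMENT_CONDITIONS[exp]}
        conds = set(EXPERIMENT_CONDITIONS[exp])
        for name in ("pupil_delta_mm", "exponent", "hr_bpm", "rmssd_ms",
                     "mep_mv", "p300_uv"):
            if not conds <= set(getattr(self, name)):
                raise ValueError(f"{name} must cover conditions {sorted(conds)}")
        if any(v < 0 for v in self.exponent.values()):
            raise ValueError("aperiodic exponents must be >= 0")

    @property
    def conditions(self) -> tuple[str, ...]:
        return EXPERIMENT_CONDITIONS[self.experiment]

    def null(self) -> "CohortConfig":
        """A copy with every condition effect removed (all-null cohort)."""
        exp = self.experiment
        flat = {c: 0.0 for c in self.conditions}
        return replace(
            self,
            pupil_delta_mm=dict(flat),
            exponent={c: 2.0 for c in self.conditions},
            hr_bpm={c: 70.0 for c in self.conditions},
            rmssd_ms={c: 40.0 for c in self.conditions},
            mep_mv={c: 1.0 for c in self.conditions},
            p300_uv={c: 5.0 for c in self.conditions},
        )


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground-truth parameter values for one synthetic participant."""

    participant: int
    latent: float
    baseline_pupil_mm: float
    pupil_delta_mm: dict[str, float]
    exponent: dict[str, float]
    hr_bpm: dict[str, float]
    rmssd_ms: dict[str, float]
    mep_mv: dict[str, float]
    p300_uv: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "participant": self.participant,
            "latent": self.latent,
            "baseline_pupil_mm": self.baseline_pupil_mm,
            "pupil_delta_mm": dict(self.pupil_delta_mm),
            "exponent": dict(self.exponent),
            "hr_bpm": dict(self.hr_bpm),
            "rmssd_ms": dict(self.rmssd_ms),
            "mep_mv": dict(self.mep_mv),
            "p300_uv": dict(self.p300_uv),
        }


def truth_rng(config: CohortConfig, participant: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, participant, 7])


def generate_truth(config: CohortConfig, participant: int) -> ParticipantTruth:
    """Draw a participant's true parameters from the cohort distribution.

    The latent factor multiplicatively scales the coupled pupil and exponent
    condition effects (``delta * (1 + z)``); all measures additionally get
    independent between-subject scatter.
    """
    rng = truth_rng(config, participant)
    z = rng.normal(0.0, config.latent_arousal_sd)
    gain = 1.0 + z
    conds = config.conditions

    baseline_pupil = float(np.clip(rng.normal(4.5, 0.5), 3.0, 6.5))
    pupil = {c: config.pupil_delta_mm[c] * gain
             + rng.normal(0, config.pupil_between_sd_mm) for c in conds}

    chi_base = float(np.clip(rng.normal(0.0, 0.1), -0.3, 0.3))
    mean_chi = float(np.mean([config.exponent[c] for c in conds]))
    chi = {}
    for c in conds:
        delta = config.exponent[c] - mean_chi
        chi[c] = max(0.1, mean_chi + chi_base + delta * gain
                     + rng.normal(0, config.exponent_between_sd))

    hr_base = float(np.clip(rng.normal(0.0, 6.0), -15, 25))
    hr = {c: config.hr_bpm[c] + hr_base
          + rng.normal(0, config.hr_between_sd_bpm) for c in conds}
    rmssd_base = float(np.clip(rng.normal(0.0, 8.0), -20, 40))
    # keep the cohort inside the alternating-jitter construction's
    # feasible region (sample RMSSD >= sqrt(2) x RR jitter)
    rmssd_floor = max(5.0, np.sqrt(2) * config.rr_jitter_sd_ms + 1.0)
    rmssd = {c: max(rmssd_floor, config.rmssd_ms[c] + rmssd_base
                    + rng.normal(0, config.rmssd_between_sd_ms))
             for c in conds}

    rest_mep = float(np.clip(rng.normal(1.0, 0.15), 0.3, None))
    base_rest = config.mep_mv.get("rest", 1.0) or 1.0
    mep = {c: max(0.05, rest_mep * (config.mep_mv[c] / base_rest
                                    + rng.normal(0, config.mep_between_sd)))
           for c in conds}
    mep["rest"] = rest_mep if "rest" in conds else mep.get("rest", rest_mep)

    p300 = {c: max(0.0, config.p300_uv[c]
                   + rng.normal(0, config.p300_between_sd_uv)) for c in conds}

    return ParticipantTruth(
        participant=participant, latent=z, baseline_pupil_mm=baseline_pupil,
        pupil_delta_mm=pupil, exponent=chi, hr_bpm=hr, rmssd_ms=rmssd,
        mep_mv={c: mep[c] for c in conds}, p300_uv=p300,
    )
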