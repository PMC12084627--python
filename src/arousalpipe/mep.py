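"""TMS-EMG processing: filtering, MEP extraction, exclusions, normalization.

The motor evoked potential (MEP) is the peak-to-peak EMG amplitude 15-60 ms
after the TMS pulse; background EMG (bgEMG) is the RMS over the 100 ms
window ending 5 ms before the pulse.  Pre- and post-pulse windows are
filtered independently so the large MEP deflection cannot smear backwards
into the background estimate.  The three-stage exclusion ledger mirrors
the study rules exactly and is order-dependent by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

BG_WINDOW_S = (-0.105, -0.005)   # relative to pulse
MEP_WINDOW_S = (0.015, 0.060)


@dataclass(frozen=True)
class EmgFilterParams:
    band_hz: tuple[float, float] = (30.0, 800.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    order: int = 4


@dataclass
class MepRecord:
    participant: int
    trial_id: int
    condition: str
    pulse_index: int                 # 1 or 2
    peak_to_peak_mv: float
    bg_rms_mv: float
    exclusion_flags: set = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.exclusion_flags)


def filter_emg(trace_mv: np.ndarray, fs_hz: float,
               params: EmgFilterParams = EmgFilterParams()) -> np.ndarray:
    """Zero-phase 30-800 Hz band-pass plus 50 Hz notch."""
    x = np.asarray(trace_mv, float)
    b, a = sps.butter(params.order,
                      np.array(params.band_hz) / (fs_hz / 2), "bandpass")
    x = sps.filtfilt(b, a, x)
    bn, an = sps.iirnotch(params.notch_hz, params.notch_q, fs=fs_hz)
    return sps.filtfilt(bn, an, x)


def _filtered_window(trace: np.ndarray, t0: float, fs: float,
                     seg_lo: float, seg_hi: float, win_lo: float,
                     win_hi: float, pulse_s: float,
                     params: EmgFilterParams) -> np.ndarray:
    """Filter [seg_lo, seg_hi] around the pulse, return [win_lo, win_hi].

    The filtered segment never crosses the pulse, so zero-phase filtering
    cannot smear post-pulse energy into pre-pulse windows or vice versa
    (filtfilt's own edge extension supplies the padding).
    """
    i0 = int(round((pulse_s + seg_lo - t0) * fs))
    i1 = int(round((pulse_s + seg_hi - t0) * fs))
    if i0 < 0 or i1 > trace.size:
        raise ValueError("analysis window exceeds EMG trace")
    filt = filter_emg(trace[i0:i1], fs, params)
    j0 = int(round((win_lo - seg_lo) * fs))
    j1 = int(round((win_hi - seg_lo) * fs))
    return filt[j0:j1]


def extract_mep(trace_mv: np.ndarray, t0_s: float, fs_hz: float,
                pulse_s: float, participant: int = 0, trial_id: int = 0,
                condition: str = "", pulse_index: int = 1,
                params: EmgFilterParams = EmgFilterParams()) -> MepRecord:
    """Peak-to-peak MEP and background RMS around one pulse.

    The pre-pulse (bgEMG) and post-pulse (MEP) windows are filtered
    separately on segments that never cross the pulse, so no filtered
    energy leaks from the MEP into the background estimate.
    """
    pre_f = _filtered_window(trace_mv, t0_s, fs_hz, -0.205, -0.005,
                             BG_WINDOW_S[0], BG_WINDOW_S[1], pulse_s, params)
    post_f = _filtered_window(trace_mv, t0_s, fs_hz, 0.005, 0.205,
                              MEP_WINDOW_S[0], MEP_WINDOW_S[1], pulse_s,
                              params)
    return MepRecord(participant, trial_id, condition, pulse_index,
                     float(post_f.max() - post_f.min()),
                     float(np.sqrt(np.mean(pre_f ** 2))))


@dataclass
class ExclusionVerdict:
    participant: int
    excluded: bool
    reason: str
    bg_diff_mv: float
    n_removed_abs: int
    n_removed_sd: int


def apply_exclusions(records: list[MepRecord],
                     abs_threshold_mv: float = 0.01,
                     sd_multiplier: float = 2.5,
                     bg_diff_threshold_mv: float = 0.001
                     ) -> tuple[list[MepRecord], list[ExclusionVerdict]]:
    """Three-stage bgEMG exclusion ledger, applied in order per participant.

    1. drop records with bgEMG RMS above ``abs_threshold_mv``;
    2. from the remainder, drop records with bgEMG above the participant's
       pooled mean + ``sd_multiplier`` sample standard deviations;
    3. exclude the participant entirely when |mean bgEMG(up) - mean
       bgEMG(down)| of the surviving records exceeds
       ``bg_diff_threshold_mv``.

    Flags are written onto the records; survivors and per-participant
    verdicts are returned.
    """
    by_p: dict[int, list[MepRecord]] = {}
    for r in records:
        by_p.setdefault(r.participant, []).append(r)

    survivors: list[MepRecord] = []
    verdicts: list[ExclusionVerdict] = []
    for p, recs in sorted(by_p.items()):
        stage1 = []
        for r in recs:
            if r.bg_rms_mv > abs_threshold_mv:
                r.exclusion_flags.add("bg_above_abs")
            else:
                stage1.append(r)
        n_abs = len(recs) - len(stage1)

        stage2 = stage1
        n_sd = 0
        if len(stage1) >= 2:
            bg = np.array([r.bg_rms_mv for r in stage1])
            thr = bg.mean() + sd_multiplier * bg.std(ddof=1)
            stage2 = []
            for r in stage1:
                if r.bg_rms_mv > thr:
                    r.exclusion_flags.add("bg_above_sd")
                    n_sd += 1
                else:
                    stage2.append(r)

        up = [r.bg_rms_mv for r in stage2 if r.condition == "up"]
        down = [r.bg_rms_mv for r in stage2 if r.condition == "down"]
        diff = abs(np.mean(up) - np.mean(down)) if up and down else np.nan
        if not stage2:
            verdicts.append(ExclusionVerdict(p, True, "no_surviving_records",
                                             diff, n_abs, n_sd))
            continue
        if np.isfinite(diff) and diff > bg_diff_threshold_mv:
            for r in stage2:
                r.exclusion_flags.add("participant_bg_diff")
            verdicts.append(ExclusionVerdict(p, True, "bg_condition_diff",
                                             diff, n_abs, n_sd))
            continue
        verdicts.append(ExclusionVerdict(p, False, "", diff, n_abs, n_sd))
        survivors.extend(stage2)
    return survivors, verdicts


def normalize_to_rest(condition_means: dict[str, float]) -> dict[str, float]:
    """up/rest and down/rest ratios for one participant."""
    rest = condition_means.get("rest")
    if rest is None or not np.isfinite(rest) or rest <= 0:
        raise ValueError("rest mean missing or non-positive")
    return {c: condition_means[c] / rest
            for c in condition_means if c != "rest"}


def bg_covariate(up_bg_mean: float, down_bg_mean: float) -> float:
    """Normalized bgEMG difference (up - down) / mean(up, down)."""
    return (up_bg_mean - down_bg_mean) / np.mean([up_bg_mean, down_bg_mean])
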