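"""Offline pupillometry preprocessing and modulation indices.

The cleaning stages follow the standard multipass pupillometry pipeline:
median-absolute-deviation (MAD) dilation-speed filtering, repeated
deviation-from-trend-line rejection, removal of temporally isolated sample
islands, eye averaging, resampling to 1000 Hz with bounded interpolation,
and zero-phase low-pass smoothing.  Baseline correction uses the last
1000 ms before modulation onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .synthetic.signals import PupilRaw


@lru_cache(maxsize=32)
def _butter_low(order: int, cutoff_hz: float, fs: float):
    return sps.butter(order, cutoff_hz / (fs / 2), "low")


@dataclass(frozen=True)
class PupilParams:
    """Parameters of the offline cleaning pipeline (units explicit)."""

    min_mm: float = 1.5
    max_mm: float = 9.0
    mad_multiplier: float = 12.0
    n_trend_passes: int = 4
    trend_cutoff_hz: float = 4.0
    island_max_ms: float = 50.0
    gap_min_ms: float = 40.0
    resample_hz: float = 1000.0
    lowpass_hz: float = 4.0
    lowpass_order: int = 3
    max_interp_gap_s: float = 2.0
    reject_missing_fraction: float = 0.5
    #: absolute floor on the trend-deviation threshold; sub-quantization
    #: residuals (eye trackers resolve ~0.01 mm) are never outliers
    deviation_floor_mm: float = 0.01
    #: absolute floor on the dilation-speed threshold; changes slower than
    #: physiological peak velocities are never outliers.  Keeps the MAD
    #: statistic from flagging genuine slow dilations on low-noise traces
    speed_floor_mm_per_s: float = 1.0


@dataclass
class CleanPupilTrace:
    """Single averaged-eye trace on a uniform 1000 Hz grid (NaN = missing)."""

    t_s: np.ndarray
    value_mm: np.ndarray
    missing_fraction: float
    rejected: bool
    fs_hz: float = 1000.0


@dataclass
class BaselineCorrectedTrace:
    """Modulation-phase trace with the pre-modulation baseline subtracted."""

    t_s: np.ndarray          # relative to modulation onset
    value_mm: np.ndarray
    baseline_mean_mm: float
    fs_hz: float = 1000.0


def _mad_threshold(x: np.ndarray, multiplier: float) -> float:
    # the 1e-9 floor keeps numerically-flat traces (MAD = 0) from having
    # femtometer-scale filter dust flagged as outliers
    med = np.median(x)
    return float(med + multiplier * np.median(np.abs(x - med)) + 1e-9)


def _speed_filter(t: np.ndarray, v: np.ndarray, valid: np.ndarray,
                  multiplier: float, floor_mm_per_s: float = 1.0
                  ) -> np.ndarray:
    idx = np.flatnonzero(valid)
    if idx.size < 3:
        return valid
    tv, vv = t[idx], v[idx]
    back = np.abs(np.diff(vv)) / np.diff(tv)
    speed = np.maximum(np.concatenate([[back[0]], back]),
                       np.concatenate([back, [back[-1]]]))
    thr = max(_mad_threshold(speed, multiplier), floor_mm_per_s)
    out = valid.copy()
    out[idx[speed > thr]] = False
    return out


def _trend(t: np.ndarray, v: np.ndarray, valid: np.ndarray, fs: float,
           cutoff_hz: float, order: int = 3) -> np.ndarray:
    idx = np.flatnonzero(valid)
    filled = np.interp(t, t[idx], v[idx])
    if filled.size > 3 * (order + 1) * 2:
        b, a = _butter_low(order, cutoff_hz, fs)
        filled = sps.filtfilt(b, a, filled)
    return filled


def _trend_filter(t: np.ndarray, v: np.ndarray, valid: np.ndarray, fs: float,
                  params: PupilParams) -> np.ndarray:
    out = valid.copy()
    for _ in range(params.n_trend_passes):
        idx = np.flatnonzero(out)
        if idx.size < 5:
            break
        trend = _trend(t, v, out, fs, params.trend_cutoff_hz)
        resid = np.abs(v[idx] - trend[idx])
        thr = max(_mad_threshold(resid, params.mad_multiplier),
                  params.deviation_floor_mm)
        bad = idx[resid > thr]
        if bad.size == 0:
            break
        out[bad] = False
    return out


def _island_filter(t: np.ndarray, valid: np.ndarray,
                   params: PupilParams) -> np.ndarray:
    """Drop valid runs <= island_max_ms isolated by gaps > gap_min_ms."""
    out = valid.copy()
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        width_ms = (t[idx[e]] - t[idx[s]]) * 1000
        gap_before = np.inf if s == 0 else (t[idx[s]] - t[idx[s - 1]]) * 1000
        gap_after = np.inf if e == idx.size - 1 else \
            (t[idx[e + 1]] - t[idx[e]]) * 1000
        if width_ms <= params.island_max_ms and \
                gap_before > params.gap_min_ms and \
                gap_after > params.gap_min_ms:
            out[idx[s]:idx[e] + 1] = False
    return out


def _clean_eye(t: np.ndarray, v: np.ndarray, valid: np.ndarray, fs: float,
               params: PupilParams) -> np.ndarray:
    ok = valid & np.isfinite(v) & (v >= params.min_mm) & (v <= params.max_mm)
    ok = _speed_filter(t, v, ok, params.mad_multiplier,
                       params.speed_floor_mm_per_s)
    ok = _trend_filter(t, v, ok, fs, params)
    ok = _island_filter(t, ok, params)
    return ok


def preprocess_pupil(raw: PupilRaw,
                     params: PupilParams = PupilParams()) -> CleanPupilTrace:
    """Clean a two-eye trace and return the averaged 1000 Hz trace.

    Eyes are cleaned independently, averaged on the common raw grid
    (single-eye value where only one eye is valid), resampled by linear
    interpolation to 1000 Hz (gaps longer than ``max_interp_gap_s`` stay
    missing) and smoothed with a zero-phase Butterworth low-pass.  The
    missing fraction is computed before interpolation; traces with more
    than half the samples missing are flagged rejected.
    """
    t = np.asarray(raw.t_s, float)
    if t.size == 0:
        raise ValueError("empty pupil trace")
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else params.resample_hz

    ok_l = _clean_eye(t, raw.left_mm, raw.valid_left, fs, params)
    ok_r = _clean_eye(t, raw.right_mm, raw.valid_right, fs, params)
    both = ok_l & ok_r
    either = ok_l | ok_r
    mean = np.full(t.size, np.nan)
    mean[both] = 0.5 * (raw.left_mm[both] + raw.right_mm[both])
    only_l = ok_l & ~ok_r
    only_r = ok_r & ~ok_l
    mean[only_l] = raw.left_mm[only_l]
    mean[only_r] = raw.right_mm[only_r]

    missing = float(np.mean(~either))
    rejected = missing > params.reject_missing_fraction

    grid = np.arange(t[0], t[-1] + 0.5 / params.resample_hz,
                     1.0 / params.resample_hz)
    idx = np.flatnonzero(either)
    if idx.size == 0:
        return CleanPupilTrace(grid, np.full(grid.size, np.nan), 1.0, True,
                               params.resample_hz)
    out = np.interp(grid, t[idx], mean[idx])
    out[(grid < t[idx[0]]) | (grid > t[idx[-1]])] = np.nan
    gaps = np.flatnonzero(np.diff(t[idx]) > params.max_interp_gap_s)
    for g in gaps:
        out[(grid > t[idx[g]]) & (grid < t[idx[g + 1]])] = np.nan

    out = _lowpass_segments(out, params)
    return CleanPupilTrace(grid, out, missing, rejected, params.resample_hz)


def _lowpass_segments(x: np.ndarray, params: PupilParams) -> np.ndarray:
    b, a = _butter_low(params.lowpass_order, params.lowpass_hz,
                       params.resample_hz)
    padlen = 3 * (max(len(a), len(b)) - 1)
    out = x.copy()
    finite = np.isfinite(x)
    i = 0
    n = x.size
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j < n and finite[j]:
            j += 1
        if j - i > padlen:
            out[i:j] = sps.filtfilt(b, a, x[i:j])
        i = j
    return out


def baseline_correct(trace: CleanPupilTrace, modulation_onset_s: float,
                     modulation_duration_s: float,
                     baseline_ms: float = 1000.0) -> BaselineCorrectedTrace:
    """Subtract the mean of the last ``baseline_ms`` before modulation onset.

    Raises when the baseline window leaves the trace or holds no finite
    sample (such trials are rejected by the caller).
    """
    t = trace.t_s
    b0 = modulation_onset_s - baseline_ms / 1000.0
    if b0 < t[0] - 1e-9 or modulation_onset_s > t[-1] + 1e-9:
        raise ValueError("baseline window outside trace")
    in_base = (t >= b0 - 1e-9) & (t < modulation_onset_s - 1e-9)
    base_vals = trace.value_mm[in_base]
    if not np.isfinite(base_vals).any():
        raise ValueError("empty baseline: trial rejected")
    baseline = float(np.nanmean(base_vals))
    in_mod = (t >= modulation_onset_s - 1e-9) & \
        (t <= modulation_onset_s + modulation_duration_s + 1e-9)
    return BaselineCorrectedTrace(t[in_mod] - modulation_onset_s,
                                  trace.value_mm[in_mod] - baseline, baseline,
                                  trace.fs_hz)


@dataclass
class ModulationIndex:
    """Up-minus-down pupil difference over the modulation window."""

    t_s: np.ndarray
    timeseries_mm: np.ndarray
    scalar_mm: float


def _stack(traces: list[BaselineCorrectedTrace], n: int) -> np.ndarray:
    return np.vstack([tr.value_mm[:n] for tr in traces])


def pupil_modulation_index(up: list[BaselineCorrectedTrace],
                           down: list[BaselineCorrectedTrace],
                           window_s: float = 15.0) -> ModulationIndex:
    """Mean up-trace minus mean down-trace per millisecond, and its average.

    With the 15 s window and the 1000 Hz grid the timeseries holds 15,000
    points; the scalar index is its mean.
    """
    if not up or not down:
        raise ValueError("need at least one accepted trial per condition")
    fs = up[0].fs_hz
    n = int(round(window_s * fs))
    for tr in up + down:
        if tr.value_mm.size < n:
            raise ValueError("trace shorter than the modulation window")
    diff = np.nanmean(_stack(up, n), axis=0) - \
        np.nanmean(_stack(down, n), axis=0)
    t = np.arange(n) / fs
    return ModulationIndex(t, diff, float(np.nanmean(diff)))


def pre_pulse_pupil(trace: BaselineCorrectedTrace, pulse_s: float,
                    window_ms: float = 150.0) -> float:
    """Mean baseline-corrected pupil size over the window before a pulse.

    Returns NaN when the window holds no finite sample.
    """
    sel = (trace.t_s >= pulse_s - window_ms / 1000.0 - 1e-9) & \
        (trace.t_s < pulse_s - 1e-9)
    vals = trace.value_mm[sel]
    if vals.size == 0 or not np.isfinite(vals).any():
        return float("nan")
    return float(np.nanmean(vals))
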