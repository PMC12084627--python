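"""Per-trial signal simulators: pupil, EEG, R-peaks, EMG.

Every simulator is a pure function of (trial, truth, config, rng) so that a
cohort is bit-reproducible from its seed.  The signals are deliberately
simple -- smooth pupil ramps, spectrally shaped Gaussian EEG, Gaussian ERP
bumps, biphasic MEP templates -- because only the features the analysis
stages measure (plateau levels, spectral exponents, windowed amplitudes,
interval statistics) need to be controlled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ..montage import CENTROPARIETAL_24, Montage
from .config import CohortConfig, ParticipantTruth
from .schedule import Trial

# --------------------------------------------------------------------------
# pupil
# --------------------------------------------------------------------------


@dataclass
class PupilRaw:
    """Two-eye raw pupil trace at the tracker rate (60 Hz)."""

    t_s: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    gaze_x_deg: np.ndarray
    gaze_y_deg: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    #: ground-truth mask of injected spike artifacts (for oracle tests)
    spike_mask: np.ndarray = field(default=None)


from functools import lru_cache


@lru_cache(maxsize=32)
def _butter(order: int, cutoff_hz: float, fs: float, btype: str):
    return sps.butter(order, cutoff_hz / (fs / 2), btype)


@lru_cache(maxsize=8)
def _butter_band(order: int, lo_hz: float, hi_hz: float, fs: float):
    return sps.butter(order, np.array([lo_hz, hi_hz]) / (fs / 2), "bandpass")


def _smooth_noise(n: int, fs: float, sd: float, cutoff_hz: float,
                  rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = _butter(2, cutoff_hz, fs, "low")
    x = sps.filtfilt(b, a, w)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_pupil_trial(trial: Trial, truth: ParticipantTruth,
                         config: CohortConfig,
                         rng: np.random.Generator) -> PupilRaw:
    """Simulate a two-eye pupil trace from instruction to modulation end.

    The baseline segment fluctuates around the participant's baseline
    diameter; during modulation the trace ramps (raised cosine, 3 s) to
    baseline + the condition's true delta and stays there.  Blink gaps mark
    both eyes invalid; spike artifacts are single valid-but-implausible
    samples recorded in ``spike_mask``.
    """
    base = truth.baseline_pupil_mm
    if not 1.5 <= base <= 9.0:
        raise ValueError("baseline pupil diameter outside [1.5, 9] mm")
    delta = truth.pupil_delta_mm[trial.condition]
    fs = config.pupil_fs_hz
    mod_on, mod_dur = trial.phases["modulation"]
    t = np.arange(0.0, mod_on + mod_dur + 0.25, 1.0 / fs)
    n = t.size

    # raised-cosine onset: self-regulation takes hold over ~1.5 s, so the
    # 15-s window mean stays within 0.05 mm of the plateau delta
    ramp_s = 1.5
    rel = np.clip((t - mod_on) / ramp_s, 0.0, 1.0)
    mean = base + delta * 0.5 * (1 - np.cos(np.pi * rel))

    common = _smooth_noise(n, fs, config.pupil_noise_sd_mm, 1.0, rng)
    left = mean + common + _smooth_noise(n, fs, 0.2 * config.pupil_noise_sd_mm,
                                         1.0, rng)
    right = mean + common + _smooth_noise(n, fs, 0.2 * config.pupil_noise_sd_mm,
                                          1.0, rng)

    valid = np.ones(n, dtype=bool)
    dur = t[-1] if n else 0.0
    n_blinks = rng.poisson(config.blink_rate_hz * dur)
    for _ in range(n_blinks):
        start = rng.uniform(0, dur)
        width = rng.uniform(0.1, 0.3)
        valid &= ~((t >= start) & (t < start + width))

    spike_mask = np.zeros(n, dtype=bool)
    n_spikes = rng.poisson(config.spike_rate_hz * dur)
    for _ in range(n_spikes):
        i = int(rng.integers(1, n - 1))
        if valid[i]:
            amp = rng.uniform(1.0, 2.0) * rng.choice([-1.0, 1.0])
            left[i] += amp
            right[i] += amp
            spike_mask[i] = True

    left = np.where(valid, left, np.nan)
    right = np.where(valid, right, np.nan)
    gaze = _smooth_noise(n, fs, 0.5, 2.0, rng), _smooth_noise(n, fs, 0.5, 2.0, rng)
    return PupilRaw(t, left, right, gaze[0], gaze[1],
                    valid.copy(), valid.copy(), spike_mask)


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------


@dataclass
class EegTrial:
    """Continuous multichannel EEG for one trial (uV)."""

    t0_s: float                    # trial-relative time of first sample
    fs_hz: float
    data: np.ndarray               # (n_channels, n_samples)
    artifact_intervals: tuple[tuple[float, float], ...]  # trial-relative s
    #: per-tone behavioral validity (exp3); empty otherwise
    behavior_ok: tuple[bool, ...] = ()

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.data.shape[1]) / self.fs_hz


def _one_over_f(n_channels: int, n: int, fs: float, chi: float,
                alpha_height_log10: float, amp_scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with one-sided PSD ``P1 * f**-chi`` (+10 Hz bump)."""
    if chi < 0:
        raise ValueError("aperiodic exponent must be >= 0")
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    p1 = (10.0 * amp_scale) ** 2  # PSD at 1 Hz, uV^2/Hz
    # power-law decay with a 1 Hz knee: the spectrum plateaus below the
    # analyzed band (physiological EEG does not diverge at DC, and an
    # unbounded f^-chi would swamp ERP baselines with slow drift)
    psd = p1 * np.maximum(freqs[nz], 1.0) ** (-chi)
    if alpha_height_log10 > 0:
        # oscillatory bump: Gaussian in log10 power at 10 Hz
        psd = psd * 10 ** (alpha_height_log10 * np.exp(
            -((freqs[nz] - 10.0) ** 2) / (2 * 1.5 ** 2)))
    shape[nz] = np.sqrt(psd * fs / 2.0)
    # draw the spectrum directly: unit-variance-per-bin complex Gaussians
    # scaled to sqrt(n) match rfft(white noise) statistics; float32
    # throughout (EEG is analyzed at uV scale, well within single precision)
    nb = freqs.size
    re = rng.standard_normal((n_channels, nb), dtype=np.float32)
    im = rng.standard_normal((n_channels, nb), dtype=np.float32)
    spec = (re + 1j * im) * (np.sqrt(n / 2.0) * shape).astype(np.float32)
    return np.fft.irfft(spec, n=n, axis=1).astype(np.float32)


def _gauss_bump(t: np.ndarray, onset: float, peak_lat: float, sigma: float,
                amp: float) -> np.ndarray:
    x = t - onset - peak_lat
    out = amp * np.exp(-x ** 2 / (2 * sigma ** 2))
    out[np.abs(x) > 4 * sigma] = 0.0
    return out


def simulate_eeg_trial(trial: Trial, truth: ParticipantTruth,
                       config: CohortConfig, montage: Montage,
                       rng: np.random.Generator,
                       alpha_height: float | None = None,
                       erp_windows_only: bool = False) -> EegTrial:
    """Continuous trial EEG: 1/f background plus tone-locked ERPs (exp3).

    The background of every channel is spectrally shaped Gaussian noise with
    power ~ f**(-chi) for the condition's true exponent, plus an optional
    10 Hz oscillatory bump.  For oddball trials, each tone adds a negative
    deflection peaking ~100 ms after onset on all channels and a late
    positive deflection peaking ~350 ms over the centroparietal subset whose
    amplitude is the condition's true P300 for targets (a small fixed value
    for standards).  Artifact bursts are drawn as a Poisson process and
    reported as time intervals; downstream bins/epochs overlapping a burst
    are flagged.
    """
    chi = truth.exponent[trial.condition]
    fs = config.eeg_fs_hz
    pad_after = 2.5 if trial.events and trial.events[0].label.startswith("tone") \
        else 0.5
    t_start = trial.phases["baseline"][0] - 0.5
    mod_on, mod_dur = trial.phases["modulation"]
    t_stop = mod_on + mod_dur + pad_after
    n = int(round((t_stop - t_start) * fs))
    if alpha_height is None:
        alpha_height = config.alpha_peak_height
    if erp_windows_only:
        # generate background only around tone epochs (independent 1/f per
        # window) -- a cheaper mode for ERP-only analyses
        data = np.zeros((montage.n_channels, n), dtype=np.float32)
        nw = int(round(1.2 * fs))
        for ev in trial.events:
            if not ev.label.startswith("tone"):
                continue
            i0 = int(round((mod_on + ev.onset_s - 0.25 - t_start) * fs))
            i0 = max(0, min(i0, n - nw))
            data[:, i0:i0 + nw] = _one_over_f(
                montage.n_channels, nw, fs, chi, alpha_height,
                config.eeg_noise_scale, rng)
    else:
        data = _one_over_f(montage.n_channels, n, fs, chi, alpha_height,
                           config.eeg_noise_scale, rng)
    t = t_start + np.arange(n) / fs

    behavior: list[bool] = []
    cp_idx = [i for i, name in enumerate(montage.names)
              if name in CENTROPARIETAL_24]
    for ev in trial.events:
        if not ev.label.startswith("tone"):
            continue
        onset = mod_on + ev.onset_s
        sl = slice(max(0, int((onset - t_start - 0.2) * fs)),
                   min(n, int((onset - t_start + 1.0) * fs)))
        data[:, sl] += _gauss_bump(t[sl], onset, 0.10, 0.04,
                                   config.n100_uv)[None, :]
        is_target = ev.label == "tone_target"
        late = truth.p300_uv[trial.condition] if is_target \
            else config.standard_p300_uv
        if cp_idx:
            data[cp_idx, sl.start:sl.stop] += _gauss_bump(
                t[sl], onset, 0.35, 0.08, late)[None, :]
        if is_target:
            behavior.append(bool(rng.random() >= config.p_miss))
        else:
            behavior.append(bool(rng.random() >= config.p_false_alarm))

    burst_len = 0.2
    lam = -np.log(max(1e-12, 1.0 - config.artifact_fraction)) / (3.0 + burst_len)
    n_bursts = rng.poisson(lam * (t_stop - t_start))
    bursts = tuple(sorted(
        (float(s), float(s + burst_len))
        for s in rng.uniform(t_start, t_stop, size=n_bursts)))
    return EegTrial(t_start, fs, data, bursts, tuple(behavior))


# --------------------------------------------------------------------------
# R-peaks
# --------------------------------------------------------------------------


def simulate_rr_series(trial: Trial, truth: ParticipantTruth,
                       config: CohortConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """R-peak times (trial-relative s) covering baseline through modulation.

    Intervals follow an alternating-jitter construction: successive RR
    intervals alternate around the mean by +-d with additional Gaussian
    jitter of SD sigma, so that E[RMSSD^2] = 4 d^2 + 2 sigma^2 equals the
    requested RMSSD^2 while the mean interval stays at 60/HR.
    """
    hr = truth.hr_bpm[trial.condition]
    rmssd_s = truth.rmssd_ms[trial.condition] / 1000.0
    if hr <= 0:
        raise ValueError("heart rate must be > 0")
    if rmssd_s < 0:
        raise ValueError("RMSSD must be >= 0")
    sigma = config.rr_jitter_sd_ms / 1000.0
    if rmssd_s ** 2 < 2 * sigma ** 2:
        raise ValueError(
            f"RMSSD {1000 * rmssd_s:.1f} ms not achievable with RR jitter SD "
            f"{1000 * sigma:.1f} ms (need RMSSD >= sqrt(2)*jitter)")
    d = 0.5 * np.sqrt(rmssd_s ** 2 - 2 * sigma ** 2)
    base = 60.0 / hr
    if base - d - 4 * sigma <= 0.05:
        raise ValueError("requested RMSSD/HR combination yields non-positive "
                         "RR intervals")
    start = trial.phases["baseline"][0]
    mod_on, mod_dur = trial.phases["modulation"]
    span = mod_on + mod_dur - start + 2 * base
    n_iv = int(np.ceil(span / (base - d))) + 2
    sign = rng.choice([-1.0, 1.0])
    alt = sign * ((-1.0) ** np.arange(n_iv))
    rr = base + alt * d + rng.normal(0, sigma, size=n_iv)
    rr = np.clip(rr, 0.05, None)
    peaks = start + rng.uniform(0, base) + np.concatenate(
        [[0.0], np.cumsum(rr)])
    return peaks[peaks <= mod_on + mod_dur + base]


# --------------------------------------------------------------------------
# EMG
# --------------------------------------------------------------------------


@dataclass
class EmgTrial:
    t0_s: float
    fs_hz: float
    data_mv: np.ndarray
    pulse_times_s: tuple[float, ...]     # trial-relative
    true_mep_mv: tuple[float, ...]       # injected peak-to-peak per pulse

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.data_mv.size) / self.fs_hz


def _mep_template(fs: float) -> np.ndarray:
    """Unit peak-to-peak biphasic deflection on [0, 80] ms post-pulse.

    Energy is confined to 15-60 ms after the pulse and to the 30-800 Hz
    band (140 Hz carrier under a 6 ms Gaussian envelope).
    """
    t = np.arange(0.0, 0.080, 1.0 / fs)
    w = np.exp(-(t - 0.033) ** 2 / (2 * 0.006 ** 2)) * np.sin(
        2 * np.pi * 140.0 * (t - 0.020))
    w[(t < 0.016) | (t > 0.059)] = 0.0
    return w / (w.max() - w.min())


def simulate_emg_trial(trial: Trial, truth: ParticipantTruth,
                       config: CohortConfig,
                       rng: np.random.Generator) -> EmgTrial:
    """EMG at 5 kHz around the modulation phase with injected MEPs.

    Background is 30-800 Hz band-limited noise at the configured RMS; each
    TMS pulse adds a biphasic deflection whose noise-free peak-to-peak is
    the condition's true MEP scaled by unit-mean lognormal trial variability.
    """
    fs = config.emg_fs_hz
    mod_on, mod_dur = trial.phases["modulation"]
    t0 = mod_on - 0.5
    n = int(round((mod_dur + 1.0) * fs))
    if config.bgemg_rms_mv > 0:
        w = rng.standard_normal(n)
        b, a = _butter_band(4, 30.0, 800.0, fs)
        noise = sps.filtfilt(b, a, w)
        noise *= config.bgemg_rms_mv / np.sqrt(np.mean(noise ** 2))
    else:
        noise = np.zeros(n)
    data = noise
    tmpl = _mep_template(fs)
    sig = config.mep_trial_cv
    pulses, amps = [], []
    for ev in trial.events:
        if ev.label != "tms_pulse":
            continue
        p = mod_on + ev.onset_s
        amp = truth.mep_mv[trial.condition] * float(
            np.exp(rng.normal(-sig ** 2 / 2, sig)))
        i0 = int(round((p - t0) * fs))
        seg = data[i0:i0 + tmpl.size]
        seg += amp * tmpl[: seg.size]
        pulses.append(p)
        amps.append(amp)
    return EmgTrial(t0, fs, data, tuple(pulses), tuple(amps))
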