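"""Heart rate and RMSSD from R-peak series, with condition indices.

R-peak detection is upstream of this package; inputs are peak times.  An
RR interval counts toward a phase only when both bounding peaks fall
inside that phase.
"""

from __future__ import annotations

import numpy as np


def phase_intervals(r_peaks_s: np.ndarray, phase_start_s: float,
                    phase_end_s: float) -> np.ndarray:
    """RR intervals whose two bounding peaks both lie inside the phase."""
    p = np.asarray(r_peaks_s, float)
    p = np.sort(p[(p >= phase_start_s) & (p <= phase_end_s)])
    iv = np.diff(p)
    if np.any(iv <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    return iv


def heart_rate(rr_intervals_s: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-interval heart rate (60 / RR) and the phase mean in bpm."""
    iv = np.asarray(rr_intervals_s, float)
    if iv.size == 0:
        return np.array([]), float("nan")
    bpm = 60.0 / iv
    return bpm, float(bpm.mean())


def rmssd(rr_intervals_s: np.ndarray) -> float:
    """Root mean square of successive RR differences, in ms."""
    iv = np.asarray(rr_intervals_s, float)
    if iv.size < 2:
        return float("nan")
    d = np.diff(iv)
    return float(np.sqrt(np.mean(d ** 2)) * 1000.0)


def cardiac_indices(up: dict[str, float], down: dict[str, float],
                    rest: dict[str, float] | None = None) -> dict[str, float]:
    """Condition-difference indices for one participant.

    With no rest condition: HR index = HR_up - HR_down and RMSSD index =
    RMSSD_down - RMSSD_up (larger = stronger condition separation).  With a
    resting control, each condition is first divided by rest.
    """
    if rest is not None:
        for key in ("hr", "rmssd"):
            if not np.isfinite(rest.get(key, np.nan)) or rest[key] == 0:
                raise ValueError(f"rest {key} missing or zero for "
                                 "normalization")
        up = {k: up[k] / rest[k] for k in ("hr", "rmssd")}
        down = {k: down[k] / rest[k] for k in ("hr", "rmssd")}
    return {"hr_index": up["hr"] - down["hr"],
            "rmssd_index": down["rmssd"] - up["rmssd"],
            "hr_up": up["hr"], "hr_down": down["hr"],
            "rmssd_up": up["rmssd"], "rmssd_down": down["rmssd"]}
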