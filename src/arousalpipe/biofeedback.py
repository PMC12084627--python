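"""Online pupil-feedback computation.

Reproduces the closed-loop scoring applied during the experiments: sample
validity (plausibility range and velocity limit), baseline-referenced
average and extreme change over the modulation phase, success
classification, and the isoluminance helper used to match stimulus colors
to the gray background.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class OnlineFilterParams:
    """Sample-validity parameters of the online loop.

    The printed velocity limit "0.0027 mm/s" is physiologically implausible
    as millimeters per second (pupillary light-reflex peak velocities are
    orders of magnitude larger), so the default reading is 0.0027 mm/ms
    (2.7 mm/s); the literal mm/s reading remains selectable via
    ``velocity_units``.
    """

    min_mm: float = 1.5
    max_mm: float = 9.0
    velocity_threshold: float = 0.0027
    velocity_units: str = "mm/ms"   # "mm/ms" or "mm/s"

    def __post_init__(self) -> None:
        if not self.min_mm < self.max_mm:
            raise ValueError("min_mm must be < max_mm")
        if self.velocity_threshold <= 0:
            raise ValueError("velocity threshold must be > 0")
        if self.velocity_units not in ("mm/ms", "mm/s"):
            raise ValueError("velocity_units must be 'mm/ms' or 'mm/s'")

    @property
    def threshold_mm_per_s(self) -> float:
        return self.velocity_threshold * (
            1000.0 if self.velocity_units == "mm/ms" else 1.0)


@dataclass(frozen=True)
class FeedbackResult:
    mean_change_mm: float
    extreme_change_mm: float
    success: bool
    color: str              # green iff success else pink
    n_valid_samples: int


def validate_sample(current_mm: float, previous_mm: float | None, dt_s: float,
                    params: OnlineFilterParams = OnlineFilterParams(),
                    blink: bool = False) -> tuple[bool, str]:
    """Validity flag and machine-readable reason for one pupil sample.

    Blink-flagged samples (the tracker's automatic detection) are rejected
    before the range test; out-of-range diameters and velocity violations
    relative to the last *valid* sample follow.  The first valid sample has
    no velocity check.
    """
    if blink or not np.isfinite(current_mm):
        return False, "blink"
    if not params.min_mm <= current_mm <= params.max_mm:
        return False, "range"
    if previous_mm is not None:
        if dt_s <= 0:
            raise ValueError("dt_s must be > 0 when a previous sample exists")
        rate = abs(current_mm - previous_mm) / dt_s
        if rate > params.threshold_mm_per_s:
            return False, "velocity"
    return True, "ok"


def validate_stream(values_mm: Sequence[float], t_s: Sequence[float],
                    params: OnlineFilterParams = OnlineFilterParams(),
                    blink: Sequence[bool] | None = None) -> np.ndarray:
    """Apply :func:`validate_sample` sequentially to a sampled trace."""
    values = np.asarray(values_mm, dtype=float)
    t = np.asarray(t_s, dtype=float)
    blink = np.zeros(values.size, bool) if blink is None else np.asarray(blink)
    valid = np.zeros(values.size, dtype=bool)
    prev_val, prev_t = None, None
    for i in range(values.size):
        dt = (t[i] - prev_t) if prev_t is not None else 1.0
        ok, _ = validate_sample(values[i], prev_val, dt, params,
                                blink=bool(blink[i]))
        valid[i] = ok
        if ok:
            prev_val, prev_t = values[i], t[i]
    return valid


def compute_feedback(baseline_mm: Iterable[float],
                     modulation_mm: Iterable[float],
                     direction: Direction | str) -> FeedbackResult:
    """Post-trial feedback from valid baseline and modulation samples.

    mean_change is the modulation average minus the baseline average;
    extreme_change is the maximum change for upregulation and the minimum
    for downregulation.  Success requires a strictly sign-correct mean
    change (an exact-zero change is unsuccessful for both directions), and
    the circle color is green exactly for success.
    """
    direction = Direction(direction)
    base = np.asarray([v for v in baseline_mm if np.isfinite(v)], float)
    mod = np.asarray([v for v in modulation_mm if np.isfinite(v)], float)
    if base.size == 0 or mod.size == 0:
        raise ValueError("feedback unavailable: no valid samples in "
                         + ("baseline" if base.size == 0 else "modulation"))
    baseline = base.mean()
    changes = mod - baseline
    mean_change = float(changes.mean())
    extreme = float(changes.max() if direction is Direction.UP
                    else changes.min())
    success = mean_change > 0 if direction is Direction.UP else mean_change < 0
    return FeedbackResult(mean_change, extreme, success,
                          "green" if success else "pink", int(mod.size))


def relative_luminance(r: float, g: float, b: float) -> float:
    """Relative luminance Y = 0.2126 R + 0.7152 G + 0.0722 B (8-bit inputs)."""
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0 <= v <= 255:
            raise ValueError(f"component {name}={v} outside [0, 255]")
    return 0.2126 * r + 0.7152 * g + 0.0722 * b
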