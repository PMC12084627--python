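"""CSV/JSON writers for generated sessions.

File contracts (all plain text):

* ``schedule.csv`` -- one row per trial event (plus one row for event-free
  trials): trial_id, condition, block, phase onsets/durations, event label,
  event onset (s, modulation-relative).
* ``pupil_raw.csv`` -- trial_id, t_ms, left_mm, right_mm, gaze, validity.
* ``eeg_header.json`` + ``eeg_epoch_<trial>.csv`` -- sampling rate, channel
  names and 2-D coordinates, artifact intervals; one wide CSV per trial.
* ``rr.csv`` -- trial_id, phase, r_peak_s.
* ``emg.csv`` -- trial_id, t_ms, amplitude_mv.
* ``truth.json`` -- the generating parameters per participant.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ParticipantData


def read_schedule(path: str | Path) -> pd.DataFrame:
    """Read a schedule.csv (one row per event; event-free trials one row)."""
    return pd.read_csv(path)


def read_rr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_emg(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_eeg(directory: str | Path):
    """Load eeg_header.json + eeg_epoch_<id>.csv into EegTrial objects.

    Returns (trials, channel names, xy coordinates); trial keys are ints.
    """
    from .signals import EegTrial

    directory = Path(directory)
    with open(directory / "eeg_header.json") as fh:
        header = json.load(fh)
    names = tuple(header["channels"])
    out = {}
    for f in sorted(directory.glob("eeg_epoch_*.csv")):
        tid = int(f.stem.split("_")[-1])
        df = pd.read_csv(f)
        data = df[list(names)].to_numpy().T
        arts = tuple((a, b) for a, b in
                     header["artifact_intervals"].get(str(tid), []))
        beh = tuple(bool(b) for b in
                    header["behavior_ok"].get(str(tid), []))
        out[tid] = EegTrial(float(header["t0_s"][str(tid)]),
                            float(header["fs_hz"]), data, arts, beh)
    return out, names, np.asarray(header["xy"])


def _phase_of(trial, t: float) -> str:
    for name, (on, dur) in trial.phases.items():
        if on <= t < on + dur:
            return name
    return "outside"


def schedule_frame(data: ParticipantData) -> pd.DataFrame:
    rows = []
    for tr in data.schedule.trials:
        base = {"participant": data.participant, "trial_id": tr.trial_id,
                "condition": tr.condition, "block": tr.block_index}
        for name, (on, dur) in tr.phases.items():
            base[f"{name}_onset_s"] = on
            base[f"{name}_duration_s"] = dur
        if tr.events:
            for ev in tr.events:
                rows.append({**base, "event": ev.label,
                             "event_onset_s": ev.onset_s})
        else:
            rows.append({**base, "event": "", "event_onset_s": np.nan})
    return pd.DataFrame(rows)


def write_participant(data: ParticipantData, out_dir: str | Path) -> None:
    out = Path(out_dir) / f"sub-{data.participant:02d}"
    out.mkdir(parents=True, exist_ok=True)
    schedule_frame(data).to_csv(out / "schedule.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(data.truth.as_dict(), fh, indent=1)

    if data.pupil is not None:
        frames = []
        for tid, tr in data.pupil.items():
            frames.append(pd.DataFrame({
                "trial_id": tid, "t_ms": np.round(tr.t_s * 1000, 3),
                "left_mm": tr.left_mm, "right_mm": tr.right_mm,
                "gaze_x_deg": tr.gaze_x_deg, "gaze_y_deg": tr.gaze_y_deg,
                "valid_left": tr.valid_left.astype(int),
                "valid_right": tr.valid_right.astype(int)}))
        pd.concat(frames).to_csv(out / "pupil_raw.csv", index=False)

    if data.eeg is not None:
        header = {
            "fs_hz": data.config.eeg_fs_hz,
            "channels": list(data.montage.names),
            "xy": data.montage.xy.tolist(),
            "artifact_intervals": {
                str(tid): list(map(list, e.artifact_intervals))
                for tid, e in data.eeg.items()},
            "behavior_ok": {str(tid): list(map(int, e.behavior_ok))
                            for tid, e in data.eeg.items()},
            "t0_s": {str(tid): e.t0_s for tid, e in data.eeg.items()},
        }
        with open(out / "eeg_header.json", "w") as fh:
            json.dump(header, fh)
        for tid, e in data.eeg.items():
            df = pd.DataFrame(np.round(e.data.T, 4),
                              columns=list(data.montage.names))
            df.insert(0, "t_ms", np.round(e.times * 1000, 3))
            df.to_csv(out / f"eeg_epoch_{tid}.csv", index=False)

    if data.rr is not None:
        rows = []
        for tid, peaks in data.rr.items():
            trial = data.schedule.trials[tid]
            for p in peaks:
                rows.append({"trial_id": tid, "phase": _phase_of(trial, p),
                             "r_peak_s": round(float(p), 4)})
        pd.DataFrame(rows).to_csv(out / "rr.csv", index=False)

    if data.emg is not None:
        frames = []
        for tid, e in data.emg.items():
            frames.append(pd.DataFrame({
                "trial_id": tid, "t_ms": np.round(e.times * 1000, 2),
                "amplitude_mv": np.round(e.data_mv, 6)}))
        pd.concat(frames).to_csv(out / "emg.csv", index=False)
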