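"""End-to-end analyses of the three experiments on generated cohorts.

Each ``run_exp*`` function streams participants from the synthetic
generator (or accepts pre-generated participants), runs the modality
pipelines, and returns tidy per-participant tables plus a group-level
test table.  Analysis defaults equal the study's printed settings; every
value is overridable through :class:`PipelineParams`.  Stage selection
exists so callers can run a subset of the analyses (e.g. only the ERP
stage in a power study); by default everything runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cardiac, erp, mep, pupil, spectral, stats
from .montage import CENTROPARIETAL_24, load_montage
from .synthetic import CohortConfig, ParticipantData, iter_participants
from .synthetic.schedule import Trial

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Analysis parameters; defaults match the study's Methods values."""

    fit_range_hz: tuple[float, float] = (30.0, 45.0)
    broadband_range_hz: tuple[float, float] = (2.0, 40.0)
    max_peaks: int = 3
    welch_fmin_hz: float = 1.0
    welch_fmax_hz: float = 45.0
    exp2_bin_s: float = 3.0
    exp2_n_mod_bins: int = 5
    exp3_bin_s: float = 0.5
    exp3_n_post_bins: int = 4
    modulation_window_s: float = 15.0
    baseline_ms: float = 1000.0
    pre_pulse_window_ms: float = 150.0
    p300_window_ms: tuple[float, float] = erp.P300_WINDOW_MS
    n100_window_ms: tuple[float, float] = erp.N100_WINDOW_MS
    p300_channels: tuple[str, ...] = CENTROPARIETAL_24
    n_perm: int = 5000
    alpha: float = 0.05
    gg_policy: str = "when_violated"
    pupil_params: pupil.PupilParams = field(default_factory=pupil.PupilParams)
    stages: tuple[str, ...] = ("pupil", "cardiac", "mep", "slope",
                               "slope_bins", "erp", "cluster", "correlations")

    def wants(self, stage: str) -> bool:
        return stage in self.stages


def _tests_frame(results: list[stats.TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"test": r.name, "statistic": r.statistic,
                     "df": r.df if not isinstance(r.df, tuple) else str(r.df),
                     "p": r.p, "effect_size": r.effect_size,
                     "effect_size_name": r.effect_size_name,
                     "mean_difference": r.mean_difference})
    return pd.DataFrame(rows)


def _participants(config: CohortConfig, participants,
                  **modalities) -> Iterable[ParticipantData]:
    """Yield supplied participants or generate only the needed modalities."""
    if participants is not None:
        return participants
    return iter_participants(config, **modalities)


# --------------------------------------------------------------------------
# shared modality helpers
# --------------------------------------------------------------------------


def _clean_modulation_traces(p: ParticipantData, params: PipelineParams
                             ) -> dict[str, list[pupil.BaselineCorrectedTrace]]:
    """Preprocess + baseline-correct all trials, grouped by condition."""
    out: dict[str, list] = {c: [] for c in p.config.conditions}
    n_rejected = 0
    for trial in p.schedule.trials:
        raw = p.pupil[trial.trial_id]
        clean = pupil.preprocess_pupil(raw, params.pupil_params)
        if clean.rejected:
            n_rejected += 1
            continue
        try:
            bc = pupil.baseline_correct(clean, trial.modulation_onset,
                                        trial.phases["modulation"][1],
                                        params.baseline_ms)
        except ValueError:
            n_rejected += 1
            continue
        out[trial.condition].append((trial, bc))
    if n_rejected:
        logger.info("participant %d: rejected %d pupil trials",
                    p.participant, n_rejected)
    return out


def _cardiac_by_condition(p: ParticipantData) -> pd.DataFrame:
    rows = []
    for trial in p.schedule.trials:
        peaks = p.rr[trial.trial_id]
        on, dur = trial.phases["modulation"]
        iv = cardiac.phase_intervals(peaks, on, on + dur)
        rows.append({"condition": trial.condition,
                     "hr": cardiac.heart_rate(iv)[1],
                     "rmssd": cardiac.rmssd(iv)})
    df = pd.DataFrame(rows)
    return df.groupby("condition", as_index=True)[["hr", "rmssd"]].mean()


def _trial_bin_powers(p: ParticipantData, trial: Trial,
                      starts_s: list[float], dur_s: float,
                      params: PipelineParams):
    """Welch power for several equal-length trial-relative bins at once.

    Returns (freqs, powers) where ``powers[k]`` is the (n_ch, n_freq)
    spectrum of bin k or None when that bin is artifact-flagged or out of
    range.  Batching all of a trial's bins into one Welch call keeps the
    per-bin overhead negligible.
    """
    eeg = p.eeg[trial.trial_id]
    fs = eeg.fs_hz
    n = int(round(dur_s * fs))
    segs, ok_idx = [], []
    for k, start in enumerate(starts_s):
        if any(a < start + dur_s and b > start
               for a, b in eeg.artifact_intervals):
            continue
        i0 = int(round((start - eeg.t0_s) * fs))
        if i0 < 0 or i0 + n > eeg.data.shape[1]:
            continue
        segs.append(eeg.data[:, i0:i0 + n])
        ok_idx.append(k)
    out = [None] * len(starts_s)
    if not segs:
        return None, out
    ps = spectral.welch_psd(np.stack(segs), fs,
                            fmin_hz=params.welch_fmin_hz,
                            fmax_hz=params.welch_fmax_hz)
    for j, k in enumerate(ok_idx):
        out[k] = ps.power[j]
    return ps.freqs_hz, out


# --------------------------------------------------------------------------
# experiment 1
# --------------------------------------------------------------------------


def run_exp1(config: CohortConfig, params: PipelineParams | None = None,
             participants: Sequence[ParticipantData] | None = None,
             strategy_labels: Mapping[int, str] | None = None) -> dict:
    """Pupil / MEP / cardiac analysis of the TMS experiment.

    Returns per-participant tables, the MEP exclusion ledger, and group
    tests: rm ANOVA on pre-pulse pupil by condition (with Holm-corrected
    pairwise tests), paired t on rest-normalized MEPs, and paired t tests
    on rest-normalized heart rate and RMSSD.  ``strategy_labels``
    (participant -> mental-strategy group) adds Holm-corrected per-group
    MEP contrasts.
    """
    params = params or PipelineParams()
    if config.experiment != "exp1":
        raise ValueError("run_exp1 needs an exp1 config")

    pupil_rows, mep_records, cardiac_rows = [], [], []
    for p in _participants(config, participants,
                           with_pupil=params.wants("pupil"),
                           with_emg=params.wants("mep"),
                           with_rr=params.wants("cardiac"),
                           with_eeg=False):
        missing = [m for m, v in (("pupil", p.pupil), ("emg", p.emg),
                                  ("rr", p.rr)) if v is None
                   and params.wants({"pupil": "pupil", "emg": "mep",
                                     "rr": "cardiac"}[m])]
        if missing:
            raise ValueError(f"missing modality: {', '.join(missing)}")
        if params.wants("pupil"):
            traces = _clean_modulation_traces(p, params)
            for cond, pairs in traces.items():
                vals = []
                for trial, bc in pairs:
                    for ev in trial.events:
                        if ev.label != "tms_pulse":
                            continue
                        v = pupil.pre_pulse_pupil(bc, ev.onset_s,
                                                  params.pre_pulse_window_ms)
                        if np.isfinite(v):
                            vals.append(v)
                pupil_rows.append({"participant": p.participant,
                                   "condition": cond,
                                   "pre_pulse_pupil_mm": np.mean(vals)
                                   if vals else np.nan,
                                   "n_pulses": len(vals)})
        if params.wants("mep"):
            for trial in p.schedule.trials:
                e = p.emg[trial.trial_id]
                for k, pulse in enumerate(e.pulse_times_s):
                    mep_records.append(mep.extract_mep(
                        e.data_mv, e.t0_s, e.fs_hz, pulse,
                        participant=p.participant, trial_id=trial.trial_id,
                        condition=trial.condition, pulse_index=k + 1))
        if params.wants("cardiac"):
            cm = _cardiac_by_condition(p)
            idx = cardiac.cardiac_indices(
                cm.loc["up"].to_dict(), cm.loc["down"].to_dict(),
                cm.loc["rest"].to_dict())
            cardiac_rows.append({"participant": p.participant, **idx})

    out: dict = {"config": config}
    tests: list[stats.TestResult] = []

    if params.wants("pupil"):
        pupil_df = pd.DataFrame(pupil_rows)
        out["pupil"] = pupil_df
        anova = stats.rm_anova(pupil_df, "pre_pulse_pupil_mm", "condition",
                               gg_policy=params.gg_policy)
        out["pupil_anova"] = anova
        wide = pupil_df.pivot(index="participant", columns="condition",
                              values="pre_pulse_pupil_mm")
        pairs = [("up", "down"), ("up", "rest"), ("down", "rest")]
        ts = [stats.paired_location_test(wide[a], wide[b],
                                         name=f"pupil {a} vs {b}")
              for a, b in pairs]
        adj = stats.holm_sequential_bonferroni([t.p for t in ts])
        posthoc = _tests_frame(ts)
        posthoc["p_holm"] = adj
        out["pupil_posthoc"] = posthoc

    if params.wants("mep"):
        survivors, verdicts = mep.apply_exclusions(mep_records)
        rec_df = pd.DataFrame([{
            "participant": r.participant, "trial_id": r.trial_id,
            "condition": r.condition, "pulse_index": r.pulse_index,
            "peak_to_peak_mv": r.peak_to_peak_mv, "bg_rms_mv": r.bg_rms_mv,
            "excluded": r.excluded,
            "flags": ";".join(sorted(r.exclusion_flags))}
            for r in mep_records])
        out["mep_records"] = rec_df
        out["mep_exclusions"] = pd.DataFrame([asdict(v) for v in verdicts])
        surv = pd.DataFrame([{"participant": r.participant,
                              "condition": r.condition,
                              "mep": r.peak_to_peak_mv,
                              "bg": r.bg_rms_mv} for r in survivors])
        norm_rows = []
        for part, g in surv.groupby("participant"):
            means = g.groupby("condition")["mep"].mean().to_dict()
            try:
                norm = mep.normalize_to_rest(means)
            except ValueError:
                continue
            bg_means = g.groupby("condition")["bg"].mean()
            norm_rows.append({
                "participant": part, "mep_up_norm": norm.get("up", np.nan),
                "mep_down_norm": norm.get("down", np.nan),
                "bg_covariate": mep.bg_covariate(bg_means.get("up", np.nan),
                                                 bg_means.get("down", np.nan))})
        mep_df = pd.DataFrame(norm_rows)
        if strategy_labels is not None:
            mep_df["strategy"] = mep_df["participant"].map(strategy_labels)
        out["mep_normalized"] = mep_df
        if len(mep_df) >= 2:
            tests.append(stats.paired_location_test(
                mep_df["mep_up_norm"], mep_df["mep_down_norm"],
                name="mep up vs down (rest-normalized)"))
        if strategy_labels is not None:
            # per-strategy-subgroup up-vs-down tests, Holm-corrected
            ts = []
            for label, g in mep_df.groupby("strategy"):
                if len(g) >= 2:
                    ts.append(stats.paired_location_test(
                        g["mep_up_norm"], g["mep_down_norm"],
                        name=f"mep up vs down [{label}]"))
            if ts:
                sub = _tests_frame(ts)
                sub["p_holm"] = stats.holm_sequential_bonferroni(sub["p"])
                out["mep_by_strategy"] = sub

    if params.wants("cardiac"):
        card_df = pd.DataFrame(cardiac_rows)
        out["cardiac"] = card_df
        tests.append(stats.paired_location_test(
            card_df["hr_up"], card_df["hr_down"],
            name="hr up vs down (rest-normalized)"))
        tests.append(stats.paired_location_test(
            card_df["rmssd_up"], card_df["rmssd_down"],
            name="rmssd up vs down (rest-normalized)"))

    out["tests"] = _tests_frame(tests)
    return out


# --------------------------------------------------------------------------
# experiment 2
# --------------------------------------------------------------------------


def _exp2_slopes(p: ParticipantData, params: PipelineParams,
                 fit_range: tuple[float, float]) -> pd.DataFrame:
    """Whole-head exponent per condition x 3-s bin (baseline + 5)."""
    cells: dict[tuple, list] = {}
    freqs = None
    bins = [("baseline", -params.exp2_bin_s)] + [
        (f"mod{i}", i * params.exp2_bin_s)
        for i in range(params.exp2_n_mod_bins)]
    for trial in p.schedule.trials:
        mod_on = trial.modulation_onset
        fr, powers = _trial_bin_powers(
            p, trial, [mod_on + rel for _, rel in bins], params.exp2_bin_s,
            params)
        freqs = fr if fr is not None else freqs
        for (name, _), power in zip(bins, powers):
            key = (trial.condition, name)
            cells.setdefault(key, [])
            if power is not None:
                cells[key].append(power)
    df = spectral.slope_for_bins(cells, freqs, fit_range,
                                 max_peaks=params.max_peaks)
    df = df.rename(columns={"key_0": "condition", "key_1": "bin"})
    df["participant"] = p.participant
    return df


def run_exp2(config: CohortConfig, params: PipelineParams | None = None,
             participants: Sequence[ParticipantData] | None = None,
             fit_range: tuple[float, float] | None = None) -> dict:
    """Pupil modulation index, spectral slope, and cardiac analysis.

    Group tests: one-sample t on the pupil modulation index, paired t on
    the condition-mean spectral slope, bin x condition rm ANOVA, paired t
    on heart rate, Wilcoxon on RMSSD, correlations among the modulation
    indices, and Meng-Rosenthal-Rubin z comparisons of the slope-index
    correlations.
    """
    params = params or PipelineParams()
    if config.experiment != "exp2":
        raise ValueError("run_exp2 needs an exp2 config")
    fit_range = fit_range or params.fit_range_hz

    pupil_rows, slope_frames, cardiac_rows = [], [], []
    for p in _participants(config, participants,
                           with_pupil=params.wants("pupil"),
                           with_eeg=params.wants("slope"),
                           with_rr=params.wants("cardiac"),
                           with_emg=False):
        if params.wants("pupil"):
            traces = _clean_modulation_traces(p, params)
            mi = pupil.pupil_modulation_index(
                [bc for _, bc in traces["up"]],
                [bc for _, bc in traces["down"]],
                params.modulation_window_s)
            up_mean = float(np.nanmean(np.concatenate(
                [bc.value_mm for _, bc in traces["up"]])))
            down_mean = float(np.nanmean(np.concatenate(
                [bc.value_mm for _, bc in traces["down"]])))
            pupil_rows.append({
                "participant": p.participant,
                "pupil_index_mm": mi.scalar_mm, "pupil_up_mm": up_mean,
                "pupil_down_mm": down_mean,
                "n_up": len(traces["up"]), "n_down": len(traces["down"])})
        if params.wants("slope"):
            slope_frames.append(_exp2_slopes(p, params, fit_range))
        if params.wants("cardiac"):
            cm = _cardiac_by_condition(p)
            idx = cardiac.cardiac_indices(cm.loc["up"].to_dict(),
                                          cm.loc["down"].to_dict())
            cardiac_rows.append({"participant": p.participant, **idx})

    out: dict = {"config": config}
    tests: list[stats.TestResult] = []

    if params.wants("pupil"):
        pupil_df = pd.DataFrame(pupil_rows)
        out["pupil"] = pupil_df
        tests.append(stats.paired_location_test(
            pupil_df["pupil_index_mm"], name="pupil modulation index vs 0"))
        tests.append(stats.paired_location_test(
            pupil_df["pupil_up_mm"], pupil_df["pupil_down_mm"],
            name="pupil up vs down"))

    if params.wants("slope"):
        slope_df = pd.concat(slope_frames, ignore_index=True)
        out["slopes"] = slope_df
        mod = slope_df[slope_df["bin"] != "baseline"]
        cond_mean = mod.groupby(["participant", "condition"])["exponent"] \
            .mean().unstack("condition")
        out["slope_condition_means"] = cond_mean
        tests.append(stats.paired_location_test(
            cond_mean["up"], cond_mean["down"], name="slope up vs down"))
        out["slope_anova"] = stats.rm_anova(
            slope_df.dropna(subset=["exponent"]), "exponent",
            ["bin", "condition"], gg_policy=params.gg_policy)
        out["slope_index"] = pd.DataFrame({
            "participant": cond_mean.index,
            "slope_index": spectral.slope_modulation_index(
                cond_mean[["up"]].to_numpy(), cond_mean[["down"]].to_numpy())})

    if params.wants("cardiac"):
        card_df = pd.DataFrame(cardiac_rows)
        out["cardiac"] = card_df
        tests.append(stats.paired_location_test(
            card_df["hr_up"], card_df["hr_down"], name="hr up vs down"))
        tests.append(stats.paired_location_test(
            card_df["rmssd_up"], card_df["rmssd_down"], method="wilcoxon",
            name="rmssd up vs down (wilcoxon)"))

    if params.wants("correlations") and params.wants("slope") and \
            params.wants("pupil") and params.wants("cardiac"):
        merged = out["slope_index"].merge(out["pupil"], on="participant") \
            .merge(out["cardiac"], on="participant")
        # the slope change is taken on the signed line slope (-chi), so a
        # positive value means the spectrum is steeper during downregulation
        merged["slope_change"] = -merged["slope_index"]
        out["indices"] = merged
        r_sp = stats.correlation(merged["slope_change"],
                                 merged["pupil_index_mm"],
                                 name="slope change x pupil index")
        r_sh = stats.correlation(merged["slope_change"], merged["hr_index"],
                                 name="slope change x hr index")
        r_sr = stats.correlation(merged["slope_change"], merged["rmssd_index"],
                                 method="spearman",
                                 name="slope change x rmssd index (spearman)")
        tests += [r_sp, r_sh, r_sr]
        n = len(merged)
        r_ph = stats.correlation(merged["pupil_index_mm"],
                                 merged["hr_index"]).statistic
        z1, p1 = stats.meng_dependent_correlation_z(
            r_sp.statistic, r_sh.statistic, r_ph, n)
        r_pr = stats.correlation(merged["pupil_index_mm"],
                                 merged["rmssd_index"]).statistic
        z2, p2 = stats.meng_dependent_correlation_z(
            r_sp.statistic, r_sr.statistic, r_pr, n)
        out["meng"] = pd.DataFrame([
            {"comparison": "slope~pupil vs slope~hr", "z": z1, "p": p1},
            {"comparison": "slope~pupil vs slope~rmssd", "z": z2, "p": p2}])

    out["tests"] = _tests_frame(tests)
    return out


# --------------------------------------------------------------------------
# experiment 3
# --------------------------------------------------------------------------


def _exp3_slopes(p: ParticipantData, params: PipelineParams) -> pd.DataFrame:
    """Exponent per condition x sound x 500-ms bin around each tone."""
    cells: dict[tuple, list] = {}
    freqs = None
    bin_names = ["baseline"] + [f"post{i}"
                                for i in range(params.exp3_n_post_bins)]
    rels = [-params.exp3_bin_s] + [i * params.exp3_bin_s
                                   for i in range(params.exp3_n_post_bins)]
    for trial in p.schedule.trials:
        mod_on = trial.modulation_onset
        tones = [ev for ev in trial.events if ev.label.startswith("tone")]
        starts = [mod_on + ev.onset_s + rel for ev in tones for rel in rels]
        fr, powers = _trial_bin_powers(p, trial, starts, params.exp3_bin_s,
                                       params)
        freqs = fr if fr is not None else freqs
        k = 0
        for ev in tones:
            sound = ev.label.removeprefix("tone_")
            for name in bin_names:
                key = (trial.condition, sound, name)
                cells.setdefault(key, [])
                if powers[k] is not None:
                    cells[key].append(powers[k])
                k += 1
    df = spectral.slope_for_bins(cells, freqs, params.fit_range_hz,
                                 max_peaks=params.max_peaks)
    df = df.rename(columns={"key_0": "condition", "key_1": "sound",
                            "key_2": "bin"})
    df["participant"] = p.participant
    return df


def run_exp3(config: CohortConfig, params: PipelineParams | None = None,
             participants: Sequence[ParticipantData] | None = None) -> dict:
    """Oddball EEG analysis: spectral slope bins, ERPs, cluster tests.

    Group tests: three-way rm ANOVA (bin x condition x sound) on the
    exponents, cluster-permutation contrasts for the P300 and N100 windows
    with Holm correction across the three condition contrasts, sound x
    condition rm ANOVA on the centroparietal 252-600 ms mean amplitude with
    Holm-corrected post-hoc tests, and the repeated-measures correlation of
    pre-tone slope with P300 amplitude (z-scored condition averages).
    """
    params = params or PipelineParams()
    if config.experiment != "exp3":
        raise ValueError("run_exp3 needs an exp3 config")
    montage = load_montage(config.n_channels)
    adjacency = montage.adjacency()
    conds = config.conditions
    # reduced montages keep whatever subset of the centroparietal set exists
    p300_channels = tuple(c for c in params.p300_channels
                          if c in montage.names) or montage.names

    slope_frames, amp_rows = [], []
    target_erps: dict[str, list[np.ndarray]] = {c: [] for c in conds}
    times = None
    for p in _participants(config, participants):
        if p.eeg is None:
            raise ValueError("missing modality: eeg")
        if params.wants("slope_bins"):
            slope_frames.append(_exp3_slopes(p, params))
        if params.wants("erp") or params.wants("cluster"):
            epochs = erp.build_epochs(p.eeg, list(p.schedule.trials),
                                      montage.names)
            times = epochs.times_s
            for cond in conds:
                avg_t = epochs.average(cond, "target")
                target_erps[cond].append(avg_t)
                for sound in ("target", "standard"):
                    avg = avg_t if sound == "target" else \
                        epochs.average(cond, "standard")
                    amp_rows.append({
                        "participant": p.participant, "condition": cond,
                        "sound": sound,
                        "p300_uv": float(erp.mean_amplitude(
                            avg, times, montage.names, params.p300_window_ms,
                            p300_channels)),
                        "n100_uv": float(erp.mean_amplitude(
                            avg, times, montage.names, params.n100_window_ms,
                            p300_channels))})

    out: dict = {"config": config}
    tests: list[stats.TestResult] = []

    if params.wants("slope_bins"):
        slope_df = pd.concat(slope_frames, ignore_index=True)
        out["slopes"] = slope_df
        out["slope_anova"] = stats.rm_anova(
            slope_df.dropna(subset=["exponent"]), "exponent",
            ["bin", "condition", "sound"], gg_policy=params.gg_policy)
        cond_mean = slope_df.groupby(["participant", "condition"])["exponent"] \
            .mean().unstack("condition")
        ts = [stats.paired_location_test(cond_mean[a], cond_mean[b],
                                         name=f"slope {a} vs {b}")
              for a, b in (("up", "down"), ("up", "control"),
                           ("down", "control"))]
        adj = stats.holm_sequential_bonferroni([t.p for t in ts])
        ph = _tests_frame(ts)
        ph["p_holm"] = adj
        out["slope_posthoc"] = ph

    if params.wants("erp"):
        amp_df = pd.DataFrame(amp_rows)
        out["p300"] = amp_df
        out["p300_anova"] = stats.rm_anova(amp_df, "p300_uv",
                                           ["sound", "condition"],
                                           gg_policy=params.gg_policy)
        tw = amp_df[amp_df["sound"] == "target"].pivot(
            index="participant", columns="condition", values="p300_uv")
        ts = [stats.paired_location_test(tw[a], tw[b],
                                         name=f"p300 target {a} vs {b}")
              for a, b in (("down", "control"), ("down", "up"),
                           ("up", "control"))]
        adj = stats.holm_sequential_bonferroni([t.p for t in ts])
        ph = _tests_frame(ts)
        ph["p_holm"] = adj
        out["p300_posthoc"] = ph

    if params.wants("cluster"):
        rng = np.random.default_rng(config.seed + 101)
        rows = []
        cluster_results = {}
        for wname, window in (("p300", params.p300_window_ms),
                              ("n100", params.n100_window_ms)):
            sel = (times * 1000 >= window[0] - 1e-6) & \
                (times * 1000 <= window[1] + 1e-6)
            contrast_ps = []
            contrasts = (("down", "control"), ("down", "up"),
                         ("up", "control"))
            for a, b in contrasts:
                res = erp.cluster_permutation_test(
                    np.stack(target_erps[a])[:, :, sel],
                    np.stack(target_erps[b])[:, :, sel],
                    adjacency, n_perm=params.n_perm, alpha=params.alpha,
                    rng=rng)
                cluster_results[(wname, a, b)] = res
                contrast_ps.append(res.min_p)
                for ci, cl in enumerate(res.clusters[:5]):
                    rows.append({"window": wname, "contrast": f"{a}-{b}",
                                 "cluster": ci, "sign": cl.sign,
                                 "mass": cl.mass, "p": cl.p,
                                 "n_points": int(cl.mask.sum())})
            holm = stats.holm_sequential_bonferroni(contrast_ps)
            for (a, b), ph in zip(contrasts, holm):
                rows.append({"window": wname, "contrast": f"{a}-{b}",
                             "cluster": -1, "sign": 0, "mass": np.nan,
                             "p": ph, "n_points": 0})
        out["clusters"] = pd.DataFrame(rows)
        out["cluster_results"] = cluster_results

    if params.wants("correlations") and params.wants("slope_bins") and \
            params.wants("erp"):
        pre = out["slopes"]
        pre = pre[(pre["sound"] == "target") & (pre["bin"] == "baseline")]
        merged = pre.merge(
            out["p300"][out["p300"]["sound"] == "target"],
            on=["participant", "condition"])
        # correlate the signed pre-tone slope (-chi) with P300 amplitude:
        # a flatter slope (higher arousal) should relate to smaller P300
        rc = stats.rm_correlation(-merged["exponent"], merged["p300_uv"],
                                  merged["participant"], z_score_within=True)
        out["rm_correlation"] = pd.DataFrame([{
            "r_rm": rc.r_rm, "df": rc.df, "p": rc.p,
            "n_subjects": rc.n_subjects, "n_obs": rc.n_obs}])

    out["tests"] = _tests_frame(tests)
    return out


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------


def write_results(result: dict, out_dir: str | Path) -> None:
    """Write every table to CSV and echo the effective config as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in result.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=isinstance(
                val.index, pd.MultiIndex) or val.index.name is not None)
    cfg = result.get("config")
    if cfg is not None:
        with open(out / "config.json", "w") as fh:
            json.dump({k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()}, fh, indent=1,
                      default=str)
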