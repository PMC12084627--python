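"""ERP epoching, averaging, and spatiotemporal cluster-permutation tests.

Epochs run -100..800 ms around tone onset at 250 Hz and are baseline
corrected to the 100 ms before onset.  Group statistics use the paired
cluster-based permutation test: point-wise paired t values are thresholded,
grouped into spatiotemporally contiguous clusters (channel neighbors from
the montage, consecutive samples in time), and cluster mass is compared to
the max-|mass| distribution over sign flips of the participant difference
waves -- the family-wise-error-controlling max statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .synthetic.schedule import Trial
from .synthetic.signals import EegTrial

logger = logging.getLogger(__name__)

EPOCH_WINDOW_S = (-0.1, 0.8)
BASELINE_WINDOW_S = (-0.1, 0.0)
P300_WINDOW_MS = (252.0, 600.0)
N100_WINDOW_MS = (52.0, 200.0)


@dataclass
class ErpEpochSet:
    """Stack of baseline-corrected epochs with per-epoch labels."""

    epochs: np.ndarray          # (n_epochs, n_channels, n_times), uV
    times_s: np.ndarray
    ch_names: tuple[str, ...]
    labels: pd.DataFrame        # condition, sound, trial_id, artifact, behavior_ok

    def select(self, condition: str | None = None,
               sound: str | None = None) -> np.ndarray:
        m = np.ones(len(self.labels), bool)
        if condition is not None:
            m &= (self.labels["condition"] == condition).to_numpy()
        if sound is not None:
            m &= (self.labels["sound"] == sound).to_numpy()
        return self.epochs[m]

    def average(self, condition: str, sound: str | None = None) -> np.ndarray:
        ep = self.select(condition, sound)
        if ep.shape[0] == 0:
            raise ValueError(f"zero surviving epochs in cell "
                             f"({condition}, {sound})")
        return ep.mean(axis=0)


def epoch_times(fs_hz: float = 250.0,
                window_s: tuple[float, float] = EPOCH_WINDOW_S) -> np.ndarray:
    n = int(round((window_s[1] - window_s[0]) * fs_hz))
    return window_s[0] + np.arange(n) / fs_hz


def build_epochs(eeg_trials: dict[int, EegTrial], trials: list[Trial],
                 ch_names: tuple[str, ...],
                 window_s: tuple[float, float] = EPOCH_WINDOW_S,
                 drop_invalid: bool = True) -> ErpEpochSet:
    """Cut tone-locked epochs, flag artifacts/behavior, baseline-correct.

    An epoch is artifact-flagged when it overlaps any of its trial's
    artifact bursts; behaviorally invalid epochs (missed targets, false
    alarms on standards) carry ``behavior_ok=False``.  With
    ``drop_invalid`` both kinds are removed and the drop counts logged per
    condition x sound.
    """
    rows, stacks = [], []
    for trial in trials:
        eeg = eeg_trials[trial.trial_id]
        fs = eeg.fs_hz
        n = int(round((window_s[1] - window_s[0]) * fs))
        tones = [ev for ev in trial.events if ev.label.startswith("tone")]
        for k, ev in enumerate(tones):
            onset = trial.modulation_onset + ev.onset_s
            i0 = int(round((onset + window_s[0] - eeg.t0_s) * fs))
            if i0 < 0 or i0 + n > eeg.data.shape[1]:
                continue
            seg = eeg.data[:, i0:i0 + n]
            lo, hi = onset + window_s[0], onset + window_s[1]
            artifact = any(a < hi and b > lo
                           for a, b in eeg.artifact_intervals)
            ok = eeg.behavior_ok[k] if k < len(eeg.behavior_ok) else True
            rows.append({"trial_id": trial.trial_id,
                         "condition": trial.condition,
                         "sound": ev.label.removeprefix("tone_"),
                         "artifact": artifact, "behavior_ok": ok})
            stacks.append(seg)
    if not stacks:
        raise ValueError("no epochs could be cut")
    epochs = np.stack(stacks)
    labels = pd.DataFrame(rows)
    times = window_s[0] + np.arange(epochs.shape[2]) / fs

    if drop_invalid:
        keep = (~labels["artifact"] & labels["behavior_ok"]).to_numpy()
        dropped = labels.loc[~keep].groupby(["condition", "sound"]).size()
        for cell, cnt in dropped.items():
            logger.info("dropped %d epochs in cell %s", cnt, cell)
        epochs, labels = epochs[keep], labels.loc[keep].reset_index(drop=True)

    base = (times >= BASELINE_WINDOW_S[0] - 1e-9) & (times < BASELINE_WINDOW_S[1])
    epochs = epochs - epochs[:, :, base].mean(axis=2, keepdims=True)
    return ErpEpochSet(epochs, times, tuple(ch_names), labels)


# --------------------------------------------------------------------------
# cluster permutation
# --------------------------------------------------------------------------


@dataclass
class Cluster:
    mask: np.ndarray            # (n_channels, n_times) membership
    mass: float                 # sum of member t values (signed)
    sign: int
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    threshold_t: float
    t_map: np.ndarray

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p < a]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def spatiotemporal_adjacency(adjacency: np.ndarray,
                             n_times: int) -> sparse.csr_matrix:
    """Sparse graph over (channel, time) points: neighbor channels at the
    same sample plus consecutive samples of the same channel."""
    n_ch = adjacency.shape[0]
    eye_t = sparse.identity(n_times, format="coo", dtype=bool)
    spatial = sparse.kron(sparse.coo_matrix(adjacency), eye_t)
    steps = sparse.diags([np.ones(n_times - 1)] * 2, [1, -1],
                         format="coo").astype(bool)
    temporal = sparse.kron(sparse.identity(n_ch, dtype=bool), steps)
    return (spatial + temporal).tocsr()


def _cluster_masses(t_flat: np.ndarray, thr: float,
                    graph: sparse.csr_matrix,
                    want_members: bool = False):
    """Signed cluster masses above the two-sided threshold.

    Returns (masses, members) with members as lists of flat indices when
    requested, else (masses, None).
    """
    masses: list[float] = []
    members: list[np.ndarray] | None = [] if want_members else None
    for sign in (1, -1):
        mask = (sign * t_flat) > thr
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        sums = np.bincount(labels, weights=t_flat[idx], minlength=n_comp)
        masses.extend(sums.tolist())
        if want_members:
            for c in range(n_comp):
                members.append(idx[labels == c])
    return masses, members


def cluster_permutation_test(cond_a: np.ndarray, cond_b: np.ndarray,
                             adjacency: np.ndarray, n_perm: int = 5000,
                             alpha: float = 0.05,
                             cluster_alpha: float = 0.05,
                             rng: np.random.Generator | None = None
                             ) -> ClusterResult:
    """Paired spatiotemporal cluster permutation test.

    ``cond_a``/``cond_b`` are participant-level averages of shape
    (n_participants, n_channels, n_times).  The cluster-forming threshold
    is the two-sided t critical value at point-wise ``cluster_alpha`` with
    df = n-1.  The null is the maximum |cluster mass| over sign flips of
    the participant difference waves -- full enumeration when 2^n <=
    ``n_perm``, otherwise Monte-Carlo draws.  Cluster p includes the
    observed statistic in its own null, guaranteeing p >= 1/(n_perm+1).
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    d = (a - b).reshape(n, -1)
    n_points = d.shape[1]
    thr = float(stats.t.ppf(1 - cluster_alpha / 2, n - 1))
    graph = spatiotemporal_adjacency(adjacency, a.shape[2])

    meansq = np.mean(d ** 2, axis=0)

    def t_maps(signs: np.ndarray) -> np.ndarray:
        m = signs @ d / n
        var = (meansq[None, :] - m ** 2) * (n / (n - 1))
        var = np.clip(var, 1e-30, None)
        return m / np.sqrt(var / n)

    t_obs = t_maps(np.ones((1, n)))[0]
    obs_masses, obs_members = _cluster_masses(t_obs, thr, graph,
                                              want_members=True)

    exhaustive = 2 ** n <= n_perm
    if exhaustive:
        bits = np.arange(2 ** n)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        signs = signs.astype(float)
        n_total = signs.shape[0]
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_total = n_perm

    null_max = np.zeros(n_total)
    chunk = 256
    for s0 in range(0, n_total, chunk):
        tm = t_maps(signs[s0:s0 + chunk])
        for j in range(tm.shape[0]):
            masses, _ = _cluster_masses(tm[j], thr, graph)
            null_max[s0 + j] = max((abs(m) for m in masses), default=0.0)

    clusters = []
    for mass, mem in zip(obs_masses, obs_members or []):
        # tolerance: the chunked null t-maps and the single observed map may
        # differ in the last float bits, but the identity permutation must
        # always count against its own cluster
        cut = abs(mass) * (1 - 1e-9) - 1e-12
        count = int(np.sum(null_max >= cut))
        p = count / n_total if exhaustive else (count + 1) / (n_total + 1)
        mask = np.zeros(n_points, bool)
        mask[mem] = True
        clusters.append(Cluster(mask.reshape(a.shape[1], a.shape[2]),
                                float(mass), 1 if mass > 0 else -1, float(p)))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters, n_total, alpha, thr,
                         t_obs.reshape(a.shape[1], a.shape[2]))


def mean_amplitude(erps: np.ndarray, times_s: np.ndarray,
                   ch_names: tuple[str, ...], window_ms: tuple[float, float],
                   channels: tuple[str, ...]) -> np.ndarray:
    """Mean amplitude over a time window and named channel set.

    ``erps`` is (..., n_channels, n_times); window endpoints are inclusive
    on the discrete grid.
    """
    erps = np.asarray(erps, float)
    for ch in channels:
        if ch not in ch_names:
            raise ValueError(f"unknown channel {ch!r}")
    ch_idx = [ch_names.index(c) for c in channels]
    t_ms = times_s * 1000.0
    sel = (t_ms >= window_ms[0] - 1e-6) & (t_ms <= window_ms[1] + 1e-6)
    return erps[..., ch_idx, :][..., sel].mean(axis=(-2, -1))
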