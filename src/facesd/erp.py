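"""ERP preprocessing, condition averaging, and cluster-based permutation tests.

The pipeline ingests *clean* epochs (channels x samples x trials, in
microvolts, linked-mastoid referenced) -- continuous-EEG artifact handling
(ICA, interpolation, manual rejection) is an upstream contract and is not
re-implemented here.  On top of the epochs it provides:

* re-referencing (linked mastoid / common average),
* zero-phase Butterworth low-pass filtering (30 Hz default),
* pre-stimulus baseline correction,
* per-participant condition averages,
* spatio-temporal cluster-based permutation tests with a sign-flip
  (within-participant condition-randomization) null, max-cluster-statistic
  multiple-comparison control, Monte Carlo p-values, Cohen's d and JZS
  Bayes factors per cluster,
* the planned region-of-interest contrasts (N170 / N250 / LPP) and the
  exploratory all-channel scans over three post-stimulus windows.

Cluster test
------------
Per (channel, sample) a paired t statistic compares the two conditions
across participants.  Samples exceeding the two-tailed critical value at
``cluster_alpha`` are grouped into clusters by temporal adjacency within a
channel and spatial adjacency across channels at the same sample; each
cluster's t values are summed.  The null distribution records, for each of
``n_perm`` random within-participant sign flips of the condition
difference, the maximum absolute cluster-level sum; the Monte Carlo p-value
of an observed cluster is ``(1 + #{null >= |sum|}) / (n_perm + 1)``.
Positive and negative clusters are formed separately and evaluated against
the same max-|statistic| null, giving a two-tailed test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal, sparse, stats
from scipy.sparse.csgraph import connected_components

from .synthdata import MASTOID_CHANNELS

__all__ = [
    "Epochs",
    "ConditionAverages",
    "RoiSpec",
    "ROI_SPECS",
    "ClusterResult",
    "rereference",
    "lowpass_butterworth",
    "baseline_correct",
    "preprocess",
    "condition_erps",
    "spatial_adjacency",
    "cluster_permutation_test",
    "roi_cluster_tests",
    "exploratory_cluster_scan",
    "cluster_effect_size",
    "roi_amplitudes",
    "EXPLORATORY_WINDOWS",
]

#: Non-overlapping exploratory scan windows partitioning the post-onset epoch.
EXPLORATORY_WINDOWS = ((0.0, 400.0), (400.0, 900.0), (900.0, 1200.0))


@dataclass
class Epochs:
    """Epoched multichannel EEG: channels x samples x trials, in microvolts.

    ``times`` are in ms relative to target-face onset and include 0.
    ``trials`` is the per-trial metadata table (participant, visibility,
    bin, delta, ...), one row per trial.
    """

    data: np.ndarray
    channel_names: list
    positions: np.ndarray
    sfreq: float
    times: np.ndarray
    trials: pd.DataFrame
    reference: str = "linked_mastoid"

    def __post_init__(self) -> None:
        n_ch, n_t, n_trials = self.data.shape
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length does not match data")
        if len(self.times) != n_t:
            raise ValueError("times length does not match data")
        if len(self.trials) != n_trials:
            raise ValueError("trial metadata length does not match data")
        if not (self.times.min() <= 0.0 <= self.times.max()):
            raise ValueError("epoch window must include stimulus onset (0 ms)")

    @property
    def scalp_picks(self) -> np.ndarray:
        return np.array(
            [i for i, ch in enumerate(self.channel_names) if ch not in MASTOID_CHANNELS]
        )

    def copy(self) -> "Epochs":
        return replace(self, data=self.data.copy(), trials=self.trials.copy())

    def time_mask(self, window_ms) -> np.ndarray:
        lo, hi = window_ms
        return (self.times >= lo) & (self.times <= hi)

    # -- on-disk format: numeric array + JSON sidecar + trials CSV ----------
    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs_data.npy", self.data)
        self.trials.to_csv(d / "epochs_trials.csv", index=False)
        meta = {
            "channel_names": list(self.channel_names),
            "positions": self.positions.tolist(),
            "sfreq": self.sfreq,
            "times_ms": self.times.tolist(),
            "reference": self.reference,
        }
        (d / "epochs_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "Epochs":
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "epochs_meta.json").read_text())
        return cls(
            data=np.load(d / "epochs_data.npy"),
            channel_names=meta["channel_names"],
            positions=np.asarray(meta["positions"]),
            sfreq=meta["sfreq"],
            times=np.asarray(meta["times_ms"]),
            trials=pd.read_csv(d / "epochs_trials.csv"),
            reference=meta["reference"],
        )


@dataclass
class ConditionAverages:
    """Per-participant, per-condition average waveforms.

    ``data`` has shape (participants, conditions, channels, samples);
    ``counts`` reports trials per participant x condition.
    """

    data: np.ndarray
    participants: list
    conditions: list
    channel_names: list
    positions: np.ndarray
    sfreq: float
    times: np.ndarray
    counts: pd.DataFrame
    reference: str = "linked_mastoid"

    def condition(self, cond) -> np.ndarray:
        return self.data[:, self.conditions.index(cond)]

    def rereference(self, scheme: str) -> "ConditionAverages":
        """Averaging and re-referencing are both linear, so a reference
        change may be applied directly to the averages."""
        new = _apply_reference(self.data, self.channel_names, scheme, ch_axis=2)
        return replace(self, data=new, reference=scheme)

    def pick_channels(self, names) -> "ConditionAverages":
        idx = [self.channel_names.index(ch) for ch in names]
        return replace(
            self,
            data=self.data[:, :, idx],
            channel_names=list(names),
            positions=self.positions[idx],
        )

    def crop(self, window_ms) -> "ConditionAverages":
        lo, hi = window_ms
        mask = (self.times >= lo) & (self.times <= hi)
        return replace(self, data=self.data[..., mask], times=self.times[mask])


def _apply_reference(data, channel_names, scheme, ch_axis=0):
    if scheme == "common_average":
        scalp = [i for i, ch in enumerate(channel_names) if ch not in MASTOID_CHANNELS]
        if len(scalp) < 2:
            raise ValueError("common average needs at least 2 scalp channels")
        ref = np.take(data, scalp, axis=ch_axis).mean(axis=ch_axis, keepdims=True)
    elif scheme == "linked_mastoid":
        mast = [i for i, ch in enumerate(channel_names) if ch in MASTOID_CHANNELS]
        if len(mast) != 2:
            raise ValueError(
                "linked-mastoid reference requires both mastoid channels "
                f"{MASTOID_CHANNELS}; found {len(mast)}"
            )
        ref = np.take(data, mast, axis=ch_axis).mean(axis=ch_axis, keepdims=True)
    else:
        raise ValueError(f"unknown reference scheme '{scheme}'")
    return data - ref


def rereference(epochs: Epochs, scheme: str) -> Epochs:
    """Re-reference epochs to the linked mastoids or the common average.

    ``linked_mastoid`` subtracts the mean of M1/M2 at every sample (a no-op
    on data already in that reference, since the mastoid channels are then
    zero-mean by construction); ``common_average`` subtracts the
    instantaneous mean over the scalp (non-mastoid) channels.  Channel
    differences are invariant under either.
    """
    data = _apply_reference(epochs.data, epochs.channel_names, scheme, ch_axis=0)
    return replace(epochs, data=data, reference=scheme)


def lowpass_butterworth(
    epochs: Epochs, cutoff: float = 30.0, order: int = 4, zero_phase: bool = True
) -> Epochs:
    """Low-pass Butterworth filter along the time axis.

    Applied forward-backward (``sosfiltfilt``) by default, giving zero phase
    shift and the squared magnitude response of the one-pass filter; DC gain
    is exactly 1.
    """
    nyq = epochs.sfreq / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=epochs.sfreq, output="sos")
    if zero_phase:
        data = signal.sosfiltfilt(sos, epochs.data, axis=1)
    else:
        data = signal.sosfilt(sos, epochs.data, axis=1)
    return replace(epochs, data=data)


def baseline_correct(epochs: Epochs, window_ms=(-200.0, 0.0)) -> Epochs:
    """Subtract the pre-stimulus mean per channel and trial.

    After correction the mean over the baseline window is exactly 0 for
    every channel x trial; the operation is idempotent.
    """
    lo, hi = window_ms
    tol = 1000.0 / epochs.sfreq  # the grid is anchored at onset, not at -200
    if lo < epochs.times.min() - tol or hi > epochs.times.max() + tol:
        raise ValueError("baseline window lies outside the epoch")
    mask = epochs.time_mask(window_ms)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, mask, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def preprocess(
    epochs: Epochs,
    lowpass_hz: float = 30.0,
    filter_order: int = 4,
    baseline_ms=(-200.0, 0.0),
) -> Epochs:
    """Standard ERP conditioning: 30 Hz zero-phase low-pass, then baseline."""
    out = lowpass_butterworth(epochs, lowpass_hz, filter_order)
    return baseline_correct(out, baseline_ms)


def condition_erps(
    epochs: Epochs,
    by=("bin",),
    keep=None,
) -> ConditionAverages:
    """Average trials into per-participant, per-condition waveforms.

    ``by`` names trial-metadata columns defining the conditions; ``keep``
    optionally restricts the condition values (e.g. the three distance
    ranges).  Participants lacking trials in some condition are dropped for
    the whole set with a warning, so every retained participant contributes
    to every condition.  Excluded trials (if flagged) are ignored.
    """
    trials = epochs.trials
    mask = np.ones(len(trials), dtype=bool)
    if "excluded" in trials.columns:
        mask &= ~trials["excluded"].to_numpy().astype(bool)
    key = list(by)
    conds = keep
    if conds is None:
        conds = sorted(
            set(map(tuple, trials.loc[mask, key].itertuples(index=False)))
        )
    else:
        conds = [c if isinstance(c, tuple) else (c,) for c in conds]
    if not conds:
        raise ValueError("no conditions to average")

    participants = sorted(trials["participant"].unique())
    keys = list(trials[key].itertuples(index=False, name=None))
    cond_masks = {c: np.array([kk == c for kk in keys]) for c in conds}
    pid = trials["participant"].to_numpy()

    data, counts, kept = [], [], []
    for p in participants:
        mats, ns = [], []
        ok = True
        for c in conds:
            sel = mask & (pid == p) & cond_masks[c]
            if not sel.any():
                ok = False
                break
            mats.append(epochs.data[:, :, sel].mean(axis=2))
            ns.append(int(sel.sum()))
        if not ok:
            warnings.warn(f"participant {p} has no trials in condition {c}; dropped")
            continue
        data.append(np.stack(mats))
        counts.extend(
            {"participant": p, "condition": c, "n_trials": n}
            for c, n in zip(conds, ns)
        )
        kept.append(p)
    if not data:
        raise ValueError("no participant has trials in every condition")
    return ConditionAverages(
        data=np.stack(data),
        participants=kept,
        conditions=[c[0] if len(c) == 1 else c for c in conds],
        channel_names=list(epochs.channel_names),
        positions=epochs.positions,
        sfreq=epochs.sfreq,
        times=epochs.times,
        counts=pd.DataFrame(counts),
        reference=epochs.reference,
    )


def spatial_adjacency(
    positions: np.ndarray, channel_names=None, threshold_frac: float = 0.55
) -> np.ndarray:
    """Channel neighbor matrix from 2D montage positions.

    Two channels are neighbors when their planar distance is below
    ``threshold_frac`` of the head radius (ear-ring radius 1).  The graph is
    symmetric with no self-edges and is validated to be connected, which the
    clustering step requires to behave like a toolbox neighbor template.
    """
    pos = np.asarray(positions, dtype=float)
    d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
    adj = (d > 0) & (d < threshold_frac)
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(sparse.csr_matrix(adj), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"adjacency graph is not connected ({n_comp} components); "
            "increase threshold_frac"
        )
    return adj


@dataclass
class ClusterResult:
    """One spatio-temporal cluster with its permutation statistics."""

    members: list  # (channel index, sample index) pairs
    channels: list  # channel names touched by the cluster
    window_ms: tuple  # first and last member time, ms
    sum_t: float
    polarity: str  # 'positive' or 'negative'
    p: float
    cohens_d: float
    bf10: float
    n_participants: int

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "window_ms": list(self.window_ms),
            "sum_t": self.sum_t,
            "polarity": self.polarity,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "bf10": self.bf10,
            "n_participants": self.n_participants,
            "members": [[int(c), int(s)] for c, s in self.members],
        }


def _grid_graph(n_ch: int, n_t: int, adjacency) -> sparse.csr_matrix:
    """Sparse adjacency over the (channel, sample) grid: temporal neighbors
    within a channel plus spatial neighbors at the same sample."""
    rows, cols = [], []
    idx = np.arange(n_ch * n_t).reshape(n_ch, n_t)
    rows.append(idx[:, :-1].ravel())
    cols.append(idx[:, 1:].ravel())
    if adjacency is not None and n_ch > 1:
        ai, aj = np.nonzero(np.triu(adjacency, 1))
        for i, j in zip(ai, aj):
            rows.append(idx[i])
            cols.append(idx[j])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    return sparse.csr_matrix(
        (np.ones(len(r), bool), (r, c)), shape=(n_ch * n_t, n_ch * n_t)
    )


def _clusters_from_mask(mask_flat, graph):
    """Connected components of the suprathreshold subgraph; returns a list of
    flat-index arrays."""
    nodes = np.flatnonzero(mask_flat)
    if len(nodes) == 0:
        return []
    sub = graph[nodes][:, nodes]
    n_comp, labels = connected_components(sub, directed=False)
    return [nodes[labels == i] for i in range(n_comp)]


def _max_cluster_stat(t_flat, thr, graph):
    best = 0.0
    for sign in (1.0, -1.0):
        for comp in _clusters_from_mask(sign * t_flat > thr, graph):
            s = abs(float(t_flat[comp].sum()))
            if s > best:
                best = s
    return best


def _paired_t(diffs_2d):
    """Columnwise one-sample t over subjects; zero-variance columns -> 0
    with a mask of valid columns."""
    n = diffs_2d.shape[0]
    mean = diffs_2d.mean(axis=0)
    sd = diffs_2d.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.zeros_like(mean)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    return t, valid


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency=None,
    times=None,
    channel_names=None,
    cluster_alpha: float = 0.05,
    n_perm: int = 10000,
    seed=None,
    compute_bf: bool = True,
) -> list:
    """Cluster-based permutation test between two paired condition averages.

    ``cond_a`` and ``cond_b`` are matched per-participant averages shaped
    (participants, channels, samples) -- or (participants, samples) for a
    single channel / ROI-averaged signal.  Returns the observed clusters
    (both polarities) sorted by Monte Carlo p, each with its summed t,
    Cohen's d and JZS BF10 computed on the per-participant mean difference
    over the cluster's members.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shapes "
                         "(matched participants)")
    if a.ndim == 2:
        a = a[:, None, :]
        b = b[:, None, :]
    n_subj, n_ch, n_t = a.shape
    if n_subj < 5:
        raise ValueError("cluster test needs at least 5 participants")
    if n_ch > 1 and adjacency is None:
        raise ValueError("adjacency required when testing multiple channels")

    d = a - b
    d2 = d.reshape(n_subj, n_ch * n_t)
    t_obs, valid = _paired_t(d2)
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} zero-variance sample(s) excluded from clustering"
        )
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, n_subj - 1)
    graph = _grid_graph(n_ch, n_t, adjacency)

    observed = []
    for sign, polarity in ((1.0, "positive"), (-1.0, "negative")):
        for comp in _clusters_from_mask((sign * t_obs > thr) & valid, graph):
            observed.append((comp, float(t_obs[comp].sum()), polarity))
    rng = np.random.default_rng(seed)
    sumsq = (d2**2).sum(axis=0)
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(1, n_ch * n_t))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_subj))
        means = signs @ d2 / n_subj
        var = (sumsq[None, :] - n_subj * means**2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = means / np.sqrt(var / n_subj)
        t_null[:, ~valid] = 0.0
        t_null[~np.isfinite(t_null)] = 0.0
        for i in range(m):
            null[done + i] = _max_cluster_stat(t_null[i], thr, graph)
        done += m

    results = []
    for comp, sum_t, polarity in observed:
        # ties (e.g. the identity permutation) count as exceedances; the
        # tolerance guards against float round-off in the vectorized t
        tol = 1e-8 * max(1.0, abs(sum_t))
        p = (1.0 + float((null >= abs(sum_t) - tol).sum())) / (n_perm + 1.0)
        subj_means = d2[:, comp].mean(axis=1)
        d_eff = cluster_effect_size(subj_means)
        bf = np.nan
        if compute_bf:
            from .inference import jzs_paired_bf

            bf = jzs_paired_bf(subj_means)
        ch_idx = sorted({int(c // n_t) for c in comp})
        s_idx = np.array(sorted({int(c % n_t) for c in comp}))
        results.append(
            ClusterResult(
                members=[(int(c // n_t), int(c % n_t)) for c in comp],
                channels=[channel_names[i] for i in ch_idx]
                if channel_names is not None
                else ch_idx,
                window_ms=(
                    (float(times[s_idx.min()]), float(times[s_idx.max()]))
                    if times is not None
                    else (int(s_idx.min()), int(s_idx.max()))
                ),
                sum_t=sum_t,
                polarity=polarity,
                p=p,
                cohens_d=d_eff,
                bf10=float(bf),
                n_participants=n_subj,
            )
        )
    return sorted(results, key=lambda r: r.p)


def cluster_effect_size(subject_diffs) -> float:
    """Cohen's d of per-participant cluster-mean differences.

    ``d = mean(diffs) / sd(diffs)``; undefined (NaN, with a warning) when
    the differences have zero variance.
    """
    v = np.asarray(subject_diffs, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences: Cohen's d undefined")
        return np.nan
    return float(v.mean() / sd)


@dataclass(frozen=True)
class RoiSpec:
    """A planned region-of-interest: channels, window, reference scheme."""

    name: str
    channels: tuple
    window_ms: tuple
    reference: str


#: The planned component ROIs: bilateral parieto-occipital sets for the
#: early face-sensitive components under the common-average reference, and
#: the centroparietal late positivity under the linked-mastoid reference.
ROI_SPECS = {
    "N170_right": RoiSpec("N170_right", ("P4", "P8", "PO10", "O2"), (140.0, 200.0), "common_average"),
    "N170_left": RoiSpec("N170_left", ("P3", "P7", "PO9", "O1"), (140.0, 200.0), "common_average"),
    "N250_right": RoiSpec("N250_right", ("P4", "P8", "PO10", "O2"), (230.0, 330.0), "common_average"),
    "N250_left": RoiSpec("N250_left", ("P3", "P7", "PO9", "O1"), (230.0, 330.0), "common_average"),
    "LPP": RoiSpec("LPP", ("Cz", "CP1", "CP2", "Pz"), (400.0, 600.0), "linked_mastoid"),
}

#: Planned contrasts: distance ranges against the middle baseline, and
#: visibility within the close and far ranges.
DISTANCE_CONTRASTS = (("far", "middle"), ("close", "middle"))
VISIBILITY_CONTRASTS = (("high", "low", "close"), ("high", "low", "far"))


def _roi_arrays(avgs: ConditionAverages, roi: RoiSpec, cond, roi_mode: str):
    sub = avgs.rereference(roi.reference).pick_channels(roi.channels).crop(roi.window_ms)
    arr = sub.condition(cond)
    if roi_mode == "average":
        arr = arr.mean(axis=1)
    return arr, sub.times


def roi_cluster_tests(
    avgs_by_bin: ConditionAverages,
    avgs_by_vis_bin: ConditionAverages = None,
    cluster_alpha: float = 0.05,
    n_perm: int = 10000,
    seed=None,
    roi_mode: str = "per_channel",
) -> dict:
    """Run the planned ROI contrasts.

    ``avgs_by_bin`` holds per-participant averages by distance range;
    ``avgs_by_vis_bin`` (optional) by (visibility, bin) for the visibility
    contrasts within the close and far ranges.  Each ROI uses its own
    reference scheme and window.  ``roi_mode='per_channel'`` clusters over
    channels x time with full within-ROI adjacency; ``'average'`` clusters
    over time on the ROI-averaged signal.  Returns a dict keyed
    ``(roi_name, contrast_label)`` -> list of :class:`ClusterResult`.
    """
    if roi_mode not in ("per_channel", "average"):
        raise ValueError("roi_mode must be 'per_channel' or 'average'")
    rng = np.random.default_rng(seed)
    out = {}
    for roi in ROI_SPECS.values():
        missing = [ch for ch in roi.channels if ch not in avgs_by_bin.channel_names]
        if missing:
            warnings.warn(
                f"ROI {roi.name} skipped: channel(s) {missing} not in montage"
            )
            continue
        full_adj = None
        if roi_mode == "per_channel":
            k = len(roi.channels)
            full_adj = np.ones((k, k), bool)
            np.fill_diagonal(full_adj, False)
        for hi, lo in DISTANCE_CONTRASTS:
            a, t = _roi_arrays(avgs_by_bin, roi, hi, roi_mode)
            b, _ = _roi_arrays(avgs_by_bin, roi, lo, roi_mode)
            out[(roi.name, f"{hi}_vs_{lo}")] = cluster_permutation_test(
                a, b,
                adjacency=full_adj,
                times=t,
                channel_names=list(roi.channels),
                cluster_alpha=cluster_alpha,
                n_perm=n_perm,
                seed=rng.integers(2**31),
            )
        if avgs_by_vis_bin is not None:
            for hi, lo, bin_ in VISIBILITY_CONTRASTS:
                a, t = _roi_arrays(avgs_by_vis_bin, roi, (hi, bin_), roi_mode)
                b, _ = _roi_arrays(avgs_by_vis_bin, roi, (lo, bin_), roi_mode)
                out[(roi.name, f"{hi}_vs_{lo}_{bin_}")] = cluster_permutation_test(
                    a, b,
                    adjacency=full_adj,
                    times=t,
                    channel_names=list(roi.channels),
                    cluster_alpha=cluster_alpha,
                    n_perm=n_perm,
                    seed=rng.integers(2**31),
                )
    return out


def exploratory_cluster_scan(
    avgs_by_bin: ConditionAverages,
    windows=EXPLORATORY_WINDOWS,
    cluster_alpha: float = 0.05,
    n_perm: int = 10000,
    seed=None,
    adjacency_threshold: float = 0.55,
) -> dict:
    """All-scalp-channel cluster scans in consecutive post-onset windows.

    Runs the distance-range contrasts over every scalp channel with
    distance-based spatial adjacency, separately in each window.  Returns a
    dict keyed ``(contrast_label, window)``.
    """
    rng = np.random.default_rng(seed)
    scalp = [ch for ch in avgs_by_bin.channel_names if ch not in MASTOID_CHANNELS]
    sub_all = avgs_by_bin.pick_channels(scalp)
    adj = spatial_adjacency(sub_all.positions, scalp, adjacency_threshold)
    out = {}
    for hi, lo in DISTANCE_CONTRASTS:
        for window in windows:
            sub = sub_all.crop(window)
            out[(f"{hi}_vs_{lo}", window)] = cluster_permutation_test(
                sub.condition(hi),
                sub.condition(lo),
                adjacency=adj,
                times=sub.times,
                channel_names=scalp,
                cluster_alpha=cluster_alpha,
                n_perm=n_perm,
                seed=rng.integers(2**31),
            )
    return out


def roi_amplitudes(avgs: ConditionAverages, roi: RoiSpec) -> pd.DataFrame:
    """Mean amplitude (uV) over a ROI's channels and window, per participant
    and condition -- the quantity entering the brain-behavior regression."""
    sub = avgs.rereference(roi.reference).pick_channels(roi.channels).crop(roi.window_ms)
    rows = []
    for i, p in enumerate(sub.participants):
        for j, c in enumerate(sub.conditions):
            rows.append(
                {
                    "participant": p,
                    "condition": c,
                    "amplitude": float(sub.data[i, j].mean()),
                }
            )
    return pd.DataFrame(rows)
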