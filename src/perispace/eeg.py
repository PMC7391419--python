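"""Global-field-power analysis of epoched multichannel EEG.

Global field power (GFP) at a time point is the standard deviation of the
trial-averaged voltages across the whole electrode montage (population
form, denominator = number of channels).  It is reference-independent:
adding a common signal to every channel leaves it unchanged.  The module
implements the standard epoch pipeline (amplitude rejection, bad-channel
interpolation, baseline correction, average reference), paired-vs-summed
multisensory contrasts (supra-/sub-additivity), time-resolved t-tests with
a consecutive-samples criterion against temporal autocorrelation, and
fixed-window condition statistics with repeated-measures ANOVAs delegated
to pingouin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

import pingouin as pg

__all__ = [
    "EpochSet",
    "GFPTrace",
    "bandpass_notch",
    "preprocess",
    "gfp",
    "summed_response",
    "subsample_trials",
    "timewise_test",
    "supraadditivity_contrast",
    "window_stats",
    "contribution_map",
]


@dataclass
class EpochSet:
    """Epoched voltages: channels x time x trials, with trial labels.

    ``tmin`` is the epoch start in seconds relative to stimulus onset;
    ``labels`` has one row per trial (columns such as modality,
    distance_index, history_label).  ``ch_pos`` (n_channels x 3) is only
    needed for bad-channel interpolation.
    """

    data: np.ndarray
    sfreq: float = 1000.0
    tmin: float = -0.2
    labels: pd.DataFrame | None = None
    bads: list = field(default_factory=list)
    ch_pos: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x time x trials")
        if self.labels is not None and len(self.labels) != self.data.shape[2]:
            raise ValueError("labels must have one row per trial")

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def times(self):
        """Sample times in seconds relative to stimulus onset."""
        return self.tmin + np.arange(self.data.shape[1]) / self.sfreq

    def average(self, mask=None) -> np.ndarray:
        """Trial-averaged voltages (channels x time), optionally over a subset."""
        if mask is None:
            return self.data.mean(axis=2)
        mask = np.asarray(mask)
        return self.data[:, :, mask].mean(axis=2)


@dataclass
class GFPTrace:
    """Per-condition GFP time series (uV, non-negative)."""

    gfp: np.ndarray
    times: np.ndarray
    condition: str = ""
    n_trials: int = 0


def bandpass_notch(epochs: EpochSet, l_freq=0.1, h_freq=40.0, notch=60.0,
                   order=4) -> EpochSet:
    """Zero-phase band-pass + notch filtering (delegated to scipy.signal).

    ``order`` is the one-way Butterworth order; forward-backward filtering
    doubles the effective order.
    """
    nyq = epochs.sfreq / 2.0
    sos = sps.butter(order, [l_freq / nyq, h_freq / nyq], btype="band", output="sos")
    data = sps.sosfiltfilt(sos, epochs.data, axis=1)
    if notch:
        b, a = sps.iirnotch(notch / nyq, Q=30.0)
        data = sps.filtfilt(b, a, data, axis=1)
    return replace(epochs, data=data)


def _interpolate_bads(data, bads, ch_pos):
    """Replace bad channels by inverse-distance weighted neighbours on the sphere."""
    if not bads:
        return data
    if ch_pos is None:
        raise ValueError("bad-channel interpolation needs channel positions")
    pos = np.asarray(ch_pos, dtype=float)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    good = np.setdiff1d(np.arange(data.shape[0]), bads)
    out = data.copy()
    for b in bads:
        # great-circle distance to good channels
        cosang = np.clip(pos[good] @ pos[b], -1.0, 1.0)
        dist = np.arccos(cosang)
        near = good[np.argsort(dist)[:4]]
        w = 1.0 / np.maximum(np.sort(dist)[:4], 1e-6)
        w /= w.sum()
        out[b] = np.tensordot(w, data[near], axes=(0, 0))
    return out


def preprocess(epochs: EpochSet, reject_uv: float = 100.0,
               baseline=(-0.2, 0.0)) -> EpochSet:
    """Reject, interpolate, baseline-correct and average-reference epochs.

    Trials in which any channel exceeds ``+/-reject_uv`` are removed; bad
    channels are reconstructed from their nearest neighbours; the mean over
    the baseline window is subtracted per channel; finally the average
    reference is applied (instantaneous channel mean becomes zero).
    """
    keep = np.all(np.abs(epochs.data) <= reject_uv, axis=(0, 1))
    if not keep.any():
        raise ValueError("all trials exceed the rejection threshold")
    data = epochs.data[:, :, keep]
    labels = epochs.labels.loc[keep].reset_index(drop=True) if epochs.labels is not None else None

    data = _interpolate_bads(data, list(epochs.bads), epochs.ch_pos)

    times = epochs.tmin + np.arange(data.shape[1]) / epochs.sfreq
    bmask = (times >= baseline[0]) & (times <= baseline[1])
    data = data - data[:, bmask, :].mean(axis=1, keepdims=True)
    data = data - data.mean(axis=0, keepdims=True)  # average reference
    return replace(epochs, data=data, labels=labels, bads=[])


def gfp(avg: np.ndarray, times=None, condition: str = "",
        n_trials: int = 0) -> GFPTrace:
    """GFP of a trial-averaged response (channels x time).

    Population standard deviation across channels at each time point.
    """
    avg = np.asarray(avg, dtype=float)
    if avg.ndim != 2 or avg.shape[0] < 2:
        raise ValueError("need a channels x time array with >= 2 channels")
    g = avg.std(axis=0, ddof=0)
    if times is None:
        times = np.arange(avg.shape[1], dtype=float)
    return GFPTrace(g, np.asarray(times), condition, n_trials)


def summed_response(avg_v: np.ndarray, avg_t: np.ndarray) -> np.ndarray:
    """Channel-wise sum of unisensory average responses ("summed" condition).

    The GFP of this sum is the additive prediction against which the paired
    visuo-tactile GFP is contrasted; note GFP(V+T) != GFP(V) + GFP(T) in
    general.
    """
    avg_v, avg_t = np.asarray(avg_v, float), np.asarray(avg_t, float)
    if avg_v.shape != avg_t.shape:
        raise ValueError("unisensory averages must have matching shape")
    return avg_v + avg_t


def subsample_trials(epochs: EpochSet, n_trials: int, seed=None) -> EpochSet:
    """Seeded random subsample of trials (count-matching control).

    Used to equate trial counts between the paired multisensory condition
    and the unisensory conditions entering the summed response, so
    signal-to-noise differences cannot masquerade as (non)linearity.
    """
    total = epochs.data.shape[2]
    if n_trials > total:
        raise ValueError("cannot subsample more trials than available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=n_trials, replace=False))
    labels = epochs.labels.iloc[keep].reset_index(drop=True) if epochs.labels is not None else None
    return replace(epochs, data=epochs.data[:, :, keep], labels=labels)


def _runs(mask, min_len):
    """Start/stop (inclusive) index pairs of True runs of at least min_len."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    for start, stop in zip(idx[0::2], idx[1::2]):
        if stop - start >= min_len:
            out.append((start, stop - 1))
    return out


def timewise_test(values: np.ndarray, times=None, mode: str = "vs-zero",
                  alpha: float = 0.01, min_consecutive: int = 10,
                  alternative: str = "two-sided"):
    """Time-resolved one-sample t-tests with a consecutive-samples criterion.

    ``values`` is subjects x time (for ``mode="paired"`` pass the per-subject
    difference).  Time points with p < ``alpha`` forming runs of at least
    ``min_consecutive`` samples are reported as (start, stop) windows in the
    units of ``times`` (sample indices when ``times`` is None).  Returns
    ``(windows, pvals)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("need a subjects x time array with >= 3 subjects")
    if mode not in ("vs-zero", "paired"):
        raise ValueError("mode must be 'vs-zero' or 'paired'")
    res = stats.ttest_1samp(values, 0.0, axis=0, alternative=alternative)
    pvals = np.asarray(res.pvalue)
    sig = pvals < alpha
    windows = _runs(sig, min_consecutive)
    if times is not None:
        times = np.asarray(times)
        windows = [(float(times[a]), float(times[b])) for a, b in windows]
    return windows, pvals


def supraadditivity_contrast(gfp_paired: np.ndarray, gfp_summed: np.ndarray,
                             times=None, alpha: float = 0.01,
                             min_consecutive: int = 10):
    """Paired-vs-summed GFP contrast across subjects.

    Inputs are subjects x time GFP arrays for the paired visuo-tactile and
    the summed (V+T) conditions.  Returns a dict with the mean difference
    trace and the significant windows split by sign: positive runs =
    supra-additive, negative = sub-additive.
    """
    gfp_paired = np.asarray(gfp_paired, float)
    gfp_summed = np.asarray(gfp_summed, float)
    if gfp_paired.shape != gfp_summed.shape:
        raise ValueError("paired and summed arrays must have matching shape")
    diff = gfp_paired - gfp_summed
    windows, pvals = timewise_test(diff, times=None, mode="paired",
                                   alpha=alpha, min_consecutive=min_consecutive)
    mean_diff = diff.mean(axis=0)
    supra, sub = [], []
    for a, b in windows:
        seg = (a, b)
        if times is not None:
            seg = (float(np.asarray(times)[a]), float(np.asarray(times)[b]))
        (supra if mean_diff[a:b + 1].mean() > 0 else sub).append(seg)
    return {"diff": mean_diff, "pvals": pvals, "supra": supra, "sub": sub}


def window_stats(gfp_by_condition: dict, times, window=(0.130, 0.150)):
    """Mean GFP per subject per condition in a fixed poststimulus window.

    ``gfp_by_condition`` maps a condition key (e.g. ``(distance, history)``
    tuples or distance indices) to a subjects x time GFP array.  Returns a
    long-format DataFrame (subject, condition columns, value) plus
    repeated-measures ANOVA table(s) delegated to pingouin when the keys
    factor into one or two factors.
    """
    times = np.asarray(times)
    wmask = (times >= window[0]) & (times <= window[1])
    if not wmask.any():
        raise ValueError("window outside the epoch")
    rows = []
    for key, arr in gfp_by_condition.items():
        arr = np.asarray(arr, dtype=float)
        means = arr[:, wmask].mean(axis=1)
        for subj, v in enumerate(means):
            if isinstance(key, tuple):
                rows.append((subj, *key, v))
            else:
                rows.append((subj, key, v))
    first_key = next(iter(gfp_by_condition))
    if isinstance(first_key, tuple) and len(first_key) == 2:
        cols = ["subject", "distance", "history", "value"]
    else:
        cols = ["subject", "condition", "value"]
    df = pd.DataFrame(rows, columns=cols)

    if "history" in cols:
        aov = pg.rm_anova(data=df, dv="value", within=["distance", "history"],
                          subject="subject", detailed=True)
    else:
        aov = pg.rm_anova(data=df, dv="value", within="condition",
                          subject="subject", detailed=True)
    pairs = pg.pairwise_tests(data=df, dv="value",
                              within=cols[1] if len(cols) == 3 else ["distance", "history"],
                              subject="subject", padjust="none")
    return df, aov, pairs


def contribution_map(epochs_by_condition: dict, times, window=(0.130, 0.150)):
    """Per-channel statistic locating which electrodes drive a window effect.

    ``epochs_by_condition`` maps condition to a subjects x channels x time
    array of averaged voltages.  For two conditions a paired t statistic per
    channel is returned; for more, a repeated-measures F statistic.  Output
    is a channel-indexed DataFrame with ``stat`` and ``pval``.
    """
    conds = list(epochs_by_condition)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    times = np.asarray(times)
    wmask = (times >= window[0]) & (times <= window[1])
    means = {c: np.asarray(a, float)[:, :, wmask].mean(axis=2)
             for c, a in epochs_by_condition.items()}  # subjects x channels
    n_channels = next(iter(means.values())).shape[1]
    if n_channels < 2:
        raise ValueError("need a multichannel montage")
    if len(conds) == 2:
        d = means[conds[0]] - means[conds[1]]
        res = stats.ttest_1samp(d, 0.0, axis=0)
        return pd.DataFrame({"channel": np.arange(n_channels),
                             "stat": res.statistic, "pval": res.pvalue})
    stacked = np.stack([means[c] for c in conds])  # cond x subj x chan
    stat = np.empty(n_channels)
    pval = np.empty(n_channels)
    for ch in range(n_channels):
        res = stats.f_oneway(*[stacked[k, :, ch] for k in range(len(conds))])
        stat[ch], pval[ch] = res.statistic, res.pvalue
    return pd.DataFrame({"channel": np.arange(n_channels), "stat": stat, "pval": pval})
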