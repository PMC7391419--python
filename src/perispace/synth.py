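"""Synthetic experiment schedules, reaction-time datasets and evoked EEG epochs.

Two behavioural designs are emulated.  The looming design delivers touch
while a visual object approaches at constant velocity from ~2 m, so tactile
onset times map linearly and negatively onto visuo-tactile distance.  The
static design flashes an LED at one of seven fixed depths with (or without)
synchronous touch on the hand.  On top of the schedules, generators draw
RTs from a distance-dependent sigmoid whose central point is shifted by the
preceding trial's disparity (the ground-truth rapid-recalibration effect),
and multichannel evoked epochs whose paired visuo-tactile response can
exceed the sum of the unisensory responses inside a configurable window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychophysics import sigmoid_eval
from .eeg import EpochSet

__all__ = [
    "LoomingDesign",
    "exp1_schedule",
    "exp2_schedule",
    "RTGeneratorParams",
    "generate_rts",
    "EEGGeneratorParams",
    "generate_eeg",
]


@dataclass(frozen=True)
class LoomingDesign:
    """Timing of the looming visuo-tactile design.

    Tactile onset is staggered from trial start; the visual object starts
    moving at ``fixation + motion_delay`` and approaches at ``velocity``,
    so disparity at touch = start_distance - velocity * (offset - motion
    onset).
    """

    fixation: float = 1.2          # s
    motion_delay: float = 0.3      # s
    start_distance: float = 200.0  # cm
    velocity: float = 75.0         # cm/s
    tactile_offsets: tuple = (1.83, 2.15, 2.47, 2.79, 3.11, 3.43)  # s from trial start
    n_experimental: int = 36       # per distance
    n_baseline: int = 8            # per offset
    n_catch: int = 36
    iti: float = 0.5               # s

    @property
    def motion_onset(self) -> float:
        return self.fixation + self.motion_delay

    def distance_at(self, offset: float) -> float:
        """Visuo-tactile distance (cm) when touch arrives at ``offset`` s."""
        if offset < self.motion_onset:
            raise ValueError("tactile offset precedes visual motion onset")
        return self.start_distance - self.velocity * (offset - self.motion_onset)


def exp1_schedule(design: LoomingDesign | None = None, seed=None) -> pd.DataFrame:
    """Build one looming-design session (300 trials by default).

    Offsets are mapped to distance indices so that D1 is the nearest
    disparity (latest touch) and D6 the farthest.  Baseline tactile trials
    reuse the same temporal offsets and inherit the equivalent distance
    index; catch trials (looming, no touch) carry none.  Columns:
    ``trial_index, modality, distance_index, offset_s, distance_cm,
    ttc_ms, rt``.
    """
    design = design or LoomingDesign()
    rng = np.random.default_rng(seed)
    offs = np.asarray(design.tactile_offsets, dtype=float)
    if np.any(np.diff(offs) <= 0):
        raise ValueError("tactile offsets must be strictly increasing")
    dist = np.array([design.distance_at(o) for o in offs])
    # latest offset = nearest disparity = D1
    dindex = {o: len(offs) - k for k, o in enumerate(offs)}

    rows = []
    for o in offs:
        d = design.distance_at(o)
        for _ in range(design.n_experimental):
            rows.append(("VT", dindex[o], o, d, d / design.velocity * 1000.0))
        for _ in range(design.n_baseline):
            rows.append(("T", dindex[o], o, d, d / design.velocity * 1000.0))
    for _ in range(design.n_catch):
        rows.append(("V", np.nan, np.nan, np.nan, np.nan))

    df = pd.DataFrame(rows, columns=["modality", "distance_index", "offset_s",
                                     "distance_cm", "ttc_ms"])
    df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    df["iti_s"] = design.iti
    df["rt"] = np.nan
    return df


EXP2_DISTANCES_CM = (3.3, 13.2, 23.1, 33.0, 42.9, 52.8, 62.9)  # D1..D7, printed labels


def exp2_schedule(blocks: int, seed=None) -> pd.DataFrame:
    """Build a static-design session of ``blocks`` blocks of 360 trials.

    Per block: 40 visuo-tactile trials at each of 7 distances, 10 visual
    catch trials at each of the 5 interior distances (D2-D6), and 30
    tactile-only trials (no disparity).  Trial order is randomised within
    block; the inter-trial interval is uniform on 1250-2250 ms.
    """
    if blocks < 0:
        raise ValueError("blocks must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for blk in range(blocks):
        rows = []
        for k in range(1, 8):
            rows += [("VT", k)] * 40
        for k in range(2, 7):
            rows += [("V", k)] * 10
        rows += [("T", np.nan)] * 30
        df = pd.DataFrame(rows, columns=["modality", "distance_index"])
        df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
        df["block"] = blk
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["modality", "distance_index", "block"])
    out.insert(0, "trial_index", np.arange(len(out)))
    out["distance_cm"] = out["distance_index"].map(
        lambda k: EXP2_DISTANCES_CM[int(k) - 1] if np.isfinite(k) else np.nan)
    out["iti_s"] = rng.uniform(1.25, 2.25, size=len(out))
    out["rt"] = np.nan
    return out


@dataclass
class RTGeneratorParams:
    """Ground truth for the behavioural RT generator.

    The visuo-tactile RT mean follows the distance sigmoid; the central
    point is shifted by +/- ``delta``/2 (distance levels) when the previous
    trial's disparity was larger/smaller than the current one, so the pooled
    curve sits between the two split curves.  Tactile-only RTs are
    distance-independent.  Noise is gamma with a fixed coefficient of
    variation (its dispersion is a modelling assumption, not an estimate).
    """

    y_min: float = 280.0   # ms, near-space RT plateau
    y_max: float = 330.0   # ms, far-space RT plateau
    x_c: float = 3.5       # distance levels
    b: float = 0.8         # levels
    delta: float = 0.0     # history shift, levels
    tactile_mean: float = 340.0  # ms
    cv: float = 0.2        # gamma coefficient of variation
    seed: int | None = None


def generate_rts(schedule: pd.DataFrame, params: RTGeneratorParams) -> pd.DataFrame:
    """Draw per-trial RTs onto a schedule.

    Requires ``modality`` and ``distance_index`` columns in session order.
    Visual catch trials get no RT.  The history shift uses the immediately
    preceding trial's disparity when both are defined (the generator-side
    analogue of the analysis split).
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(params.seed)
    out = schedule.copy()
    d = pd.to_numeric(out["distance_index"], errors="coerce").to_numpy(dtype=float)
    prev = np.concatenate(([np.nan], d[:-1]))
    shape = 1.0 / params.cv**2 if params.cv > 0 else np.inf

    rts = np.full(len(out), np.nan)
    for i, mod in enumerate(out["modality"]):
        if mod == "V":
            continue
        if mod == "T":
            mu = params.tactile_mean
        else:
            xc = params.x_c
            if np.isfinite(prev[i]) and np.isfinite(d[i]):
                if prev[i] > d[i]:
                    xc = params.x_c + params.delta / 2.0
                elif prev[i] < d[i]:
                    xc = params.x_c - params.delta / 2.0
            mu = float(sigmoid_eval(d[i], params.y_min, params.y_max, xc, params.b))
        if params.cv > 0:
            rts[i] = rng.gamma(shape, mu / shape)
        else:
            rts[i] = mu
    out["rt"] = rts
    return out


@dataclass
class EEGGeneratorParams:
    """Ground truth for the evoked-epoch generator.

    Unisensory epochs are a fixed channel topography times a canonical
    waveform plus white noise.  Paired visuo-tactile epochs are the channel-
    wise sum of the two unisensory signals, scaled by a gain inside
    ``gain_window``; ``gain == 1`` is the exact additive model.  The gain
    may depend on distance (decreasing) and preceding-trial history.
    """

    n_channels: int = 128
    sfreq: float = 1000.0
    tmin: float = -0.2     # s
    tmax: float = 0.8      # s (exclusive of last sample + 1/sfreq)
    n_trials: int = 40     # per condition
    noise_sd: float = 1.0  # uV
    gain: float = 1.0      # VT gain inside the window
    gain_window: tuple = (0.124, 0.158)  # s
    v_latency: float = 0.100   # s, visual waveform peak
    t_latency: float = 0.080   # s, tactile waveform peak
    amplitude: float = 5.0     # uV
    seed: int | None = None


def _waveform(times, latency, width=0.025):
    return np.exp(-0.5 * ((times - latency) / width) ** 2) * (times > 0)


def _topography(rng, n_channels):
    topo = rng.standard_normal(n_channels)
    topo -= topo.mean()
    return topo / np.linalg.norm(topo) * np.sqrt(n_channels)


def generate_eeg(params: EEGGeneratorParams,
                 conditions=None) -> dict[str, EpochSet]:
    """Generate evoked epochs for unisensory and paired conditions.

    ``conditions`` maps a label to a gain factor applied to the VT response
    inside the gain window (default: one "VT" condition with ``params.gain``);
    "V" and "T" unisensory sets are always produced.  Returns a dict of
    :class:`~perispace.eeg.EpochSet`.
    """
    rng = np.random.default_rng(params.seed)
    n_times = int(round((params.tmax - params.tmin) * params.sfreq))
    times = params.tmin + np.arange(n_times) / params.sfreq

    topo_v = _topography(rng, params.n_channels)
    topo_t = _topography(rng, params.n_channels)
    sig_v = params.amplitude * np.outer(topo_v, _waveform(times, params.v_latency))
    sig_t = params.amplitude * np.outer(topo_t, _waveform(times, params.t_latency))

    if conditions is None:
        conditions = {"VT": params.gain}
    for g in conditions.values():
        if g < 0:
            raise ValueError("gain must be non-negative")

    in_win = (times >= params.gain_window[0]) & (times <= params.gain_window[1])

    def epochs(signal, label):
        data = signal[:, :, None] + params.noise_sd * rng.standard_normal(
            (params.n_channels, n_times, params.n_trials))
        labels = pd.DataFrame({"modality": [label] * params.n_trials})
        return EpochSet(data, sfreq=params.sfreq, tmin=params.tmin, labels=labels)

    out = {"V": epochs(sig_v, "V"), "T": epochs(sig_t, "T")}
    for label, gain in conditions.items():
        sig_vt = sig_v + sig_t
        sig_vt = np.where(in_win[None, :], gain * sig_vt, sig_vt)
        out[label] = epochs(sig_vt, "VT")
    return out
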