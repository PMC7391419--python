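"""Simulation engine for the Hebbian visuo-tactile peri-personal-space network.

State evolves by explicit Euler integration at a fixed 1 ms step: each
neuron low-pass filters its net input (membrane time constant ``tau``) and
passes the state through a sigmoidal activation.  Unisensory net input is
external drive + Mexican-hat lateral input + feedback from the multisensory
neuron; the multisensory neuron sums unisensory activities through the
plastic feedforward weights.  After every step the feedforward weights are
updated by the gated Hebbian rule with exponential forgetting toward their
basal values.  The network's "reaction time" on a trial is the first time,
from tactile stimulus onset, at which the summed tactile-sheet activity
reaches the detection threshold ``p_th``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .config import GridSpec, NetworkConfig, StimulusSpec, default_config

__all__ = [
    "NetworkState",
    "PPSNetwork",
    "build_network",
    "external_input",
    "decode_rt",
    "session_schedule",
    "run_session",
]

_RT_TIMEOUT = np.nan  # sentinel for trials that never reach threshold


@dataclass
class NetworkState:
    """Snapshot of the mutable network state at one time step."""

    q_tactile: np.ndarray
    z_tactile: np.ndarray
    q_visual: np.ndarray
    z_visual: np.ndarray
    q_multi: float
    z_multi: float
    w_tactile: np.ndarray
    w_visual: np.ndarray
    t_now: float


def _grid_axes(grid: GridSpec, modality: str):
    """Receptive-field centre coordinates along each axis of a sheet (cm)."""
    n = grid.n_per_side
    if modality == "tactile":
        ax = np.arange(n) * grid.tactile_spacing
        return ax, ax
    depth = np.arange(n) * grid.visual_spacing
    lateral = (np.arange(n) - (n - 1) / 2.0) * grid.visual_spacing
    return depth, lateral


def external_input(stim: StimulusSpec, grid: GridSpec, t_ms: float,
                   rf_sigma: float) -> np.ndarray:
    """Input map e(t): the stimulus filtered by the neurons' receptive fields.

    The stimulus Gaussian (width ``stim.sigma``) convolved with a Gaussian
    receptive field (width ``rf_sigma``) is again Gaussian with combined
    width, so the map is evaluated directly; it peaks at the neuron whose
    receptive-field centre is closest to the stimulus position and is zero
    outside [onset, offset].
    """
    n = grid.n_per_side
    if not (stim.onset <= t_ms < stim.offset):
        return np.zeros((n, n))
    sigma = float(np.hypot(stim.sigma, rf_sigma))
    if stim.modality == "tactile":
        ax0, ax1 = _grid_axes(grid, "tactile")
        if stim.position is None:
            pos = (ax0[-1] / 2.0, ax1[-1] / 2.0)  # centre of the skin patch
        elif np.isscalar(stim.position):
            pos = (float(stim.position), ax1[-1] / 2.0)
        else:
            pos = tuple(map(float, stim.position))
    else:
        depth = (stim.distance_at(t_ms) if stim.start_distance is not None
                 else float(stim.position))
        pos = (depth, 0.0)
        ax0, ax1 = _grid_axes(grid, "visual")
    if pos[0] > ax0[-1] + 3 * sigma or pos[0] < ax0[0] - 3 * sigma:
        warnings.warn("stimulus outside the represented space; zero input map")
        return np.zeros((n, n))
    f0 = np.exp(-((ax0 - pos[0]) ** 2) / (2 * sigma**2))
    f1 = np.exp(-((ax1 - pos[1]) ** 2) / (2 * sigma**2))
    return stim.amplitude * np.outer(f0, f1)


def decode_rt(trace, p_th: float, dt: float = 1.0):
    """First time (ms from tactile onset) summed tactile activity reaches p_th.

    ``trace`` is sampled every ``dt`` ms starting at tactile stimulus onset.
    Returns NaN (timeout sentinel) if the threshold is never reached.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty activity trace")
    above = trace >= p_th
    if not above.any():
        return _RT_TIMEOUT
    return float(np.argmax(above) * dt)


class _SeparableDoG:
    """Difference-of-Gaussians lateral coupling via separable Gaussian passes.

    A 2-D Gaussian convolution with zero padding factorises into two 1-D
    passes; on a fixed n x n sheet each pass is a banded n x n matrix, so
    the whole Mexican-hat coupling reduces to A_ex*Ge z Ge - A_in*Gi z Gi
    with symmetric precomputed matrices.
    """

    def __init__(self, kernel, n):
        idx = np.arange(n)
        d2 = (idx[:, None] - idx[None, :]) ** 2
        self.parts = []
        for amp, sig in ((kernel.exc_amp, kernel.exc_sigma),
                         (-kernel.inh_amp, kernel.inh_sigma)):
            if amp == 0 or sig <= 0:
                continue
            g = np.exp(-d2 / (2 * sig**2))
            g[d2 > (4 * sig) ** 2] = 0.0  # truncate at 4 sigma, as a finite kernel
            self.parts.append((amp, g))

    def __call__(self, z):
        out = 0.0
        for amp, g in self.parts:
            out = out + amp * (g @ z @ g)
        return out


class PPSNetwork:
    """The visuo-tactile network with plastic feedforward convergence.

    Weights persist across trials (plasticity is the only cross-trial
    memory); membrane state is reset to rest at trial start.  All dynamics
    are deterministic — stochasticity enters only through the trial
    schedule.
    """

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or default_config()
        c = self.config
        n = c.grid.n_per_side

        depth, lateral = _grid_axes(c.grid, "visual")
        lat_off = np.maximum(np.abs(lateral) - c.grid.face_halfwidth, 0.0)
        self.visual_face_distance = np.hypot(depth[:, None], lat_off[None, :])

        self.w_tactile_basal = np.full((n, n), c.feedforward.w0_tactile)
        self.w_visual_basal = c.feedforward.w0_visual * np.exp(
            -self.visual_face_distance / c.feedforward.lambda_v)
        self.w_tactile_max = c.feedforward.w0_tactile
        self.w_visual_max = c.feedforward.w0_visual

        self.b_tactile = np.full((n, n), c.feedback.b0_tactile)
        self.b_visual = c.feedback.b0_visual * np.exp(
            -self.visual_face_distance / c.feedforward.lambda_v)

        self._lat_t = _SeparableDoG(c.lateral_tactile, n)
        self._lat_v = _SeparableDoG(c.lateral_visual, n)
        self._gate_theta = c.hebbian.gate_theta * c.multi.f_max

        self.reset_weights()
        self.reset_state()

    # -- state management -------------------------------------------------

    def reset_state(self):
        """Return membrane state to rest (q = 0) without touching the weights."""
        n = self.config.grid.n_per_side
        self.q_tactile = np.zeros((n, n))
        self.q_visual = np.zeros((n, n))
        self.q_multi = 0.0
        self.z_tactile = self.config.tactile.activation(self.q_tactile)
        self.z_visual = self.config.visual.activation(self.q_visual)
        self.z_multi = float(self.config.multi.activation(self.q_multi))
        self.t_now = 0.0

    def reset_weights(self):
        """Return the plastic feedforward weights to their basal maps."""
        self.w_tactile = self.w_tactile_basal.copy()
        self.w_visual = self.w_visual_basal.copy()

    def state(self) -> NetworkState:
        return NetworkState(self.q_tactile.copy(), self.z_tactile.copy(),
                            self.q_visual.copy(), self.z_visual.copy(),
                            self.q_multi, self.z_multi,
                            self.w_tactile.copy(), self.w_visual.copy(),
                            self.t_now)

    # -- dynamics ----------------------------------------------------------

    def step(self, e_tactile, e_visual, learn: bool = True):
        """One explicit-Euler step of the membrane/activation dynamics.

        Net inputs are computed from the current activities, state variables
        are relaxed toward them, activations refreshed, and (optionally) the
        Hebbian update applied.
        """
        c = self.config
        dt = c.sim.dt

        lat_t = self._lat_t(self.z_tactile) if self.z_tactile.max() > 1e-7 else 0.0
        lat_v = self._lat_v(self.z_visual) if self.z_visual.max() > 1e-7 else 0.0
        u_t = e_tactile + lat_t + self.b_tactile * self.z_multi
        u_v = e_visual + lat_v + self.b_visual * self.z_multi
        u_m = float(np.sum(self.w_tactile * self.z_tactile)
                    + np.sum(self.w_visual * self.z_visual))

        self.q_tactile += (dt / c.tactile.tau) * (u_t - self.q_tactile)
        self.q_visual += (dt / c.visual.tau) * (u_v - self.q_visual)
        self.q_multi += (dt / c.multi.tau) * (u_m - self.q_multi)
        if not np.isfinite(self.q_multi) or not np.isfinite(self.q_tactile).all():
            raise FloatingPointError("non-finite network state; trial aborted")

        self.z_tactile = c.tactile.activation(self.q_tactile)
        self.z_visual = c.visual.activation(self.q_visual)
        self.z_multi = float(c.multi.activation(self.q_multi))
        self.t_now += dt
        if learn:
            self.hebbian_update()

    def hebbian_update(self):
        """Gated Hebbian reinforcement plus unconditional forgetting.

        dW = rho0 * (W_max - W) * z_pre * (z_multi - theta)^+  -  k_h * (W - W(0));
        the reinforcement rate vanishes at the ceiling, the forgetting term
        decays W exponentially toward its basal map regardless of activity.
        """
        h = self.config.hebbian
        gate = self.z_multi - self._gate_theta
        if gate > 0:
            self.w_tactile += (h.rho0_tactile * (self.w_tactile_max - self.w_tactile)
                               * self.z_tactile * gate)
            self.w_visual += (h.rho0_visual * (self.w_visual_max - self.w_visual)
                              * self.z_visual * gate)
        k = h.k_h
        self.w_tactile += -k * (self.w_tactile - self.w_tactile_basal)
        self.w_visual += -k * (self.w_visual - self.w_visual_basal)

    def idle(self, duration_s: float):
        """Stimulus-free time: apply the closed-form forgetting decay.

        With the network at rest no reinforcement occurs, so n update steps
        scale (W - W(0)) by (1 - k_h)^n exactly; applied directly instead of
        stepping through the gap.
        """
        if duration_s <= 0:
            return
        n_steps = int(round(duration_s * 1000.0 / self.config.hebbian.update_dt))
        factor = (1.0 - self.config.hebbian.k_h) ** n_steps
        self.w_tactile = self.w_tactile_basal + factor * (self.w_tactile - self.w_tactile_basal)
        self.w_visual = self.w_visual_basal + factor * (self.w_visual - self.w_visual_basal)

    # -- trials ------------------------------------------------------------

    def run_trial(self, visual_stim: StimulusSpec | None, tactile_onset: float,
                  learn: bool = True) -> dict:
        """Simulate one trial and decode the network RT.

        The trial clock starts at visual motion onset (t = 0); the tactile
        Gaussian input turns on at ``tactile_onset`` (ms) for the configured
        duration, and simulation runs to ``tactile_onset + post_window``.
        Membrane state starts from rest; weights carry over from preceding
        trials and keep updating every step.  Returns the decoded RT (NaN on
        timeout) and the visuo-tactile distance at tactile onset.
        """
        c = self.config
        sim = c.sim
        self.reset_state()

        tact = StimulusSpec(**{**c.tactile_stimulus.__dict__,
                               "onset": tactile_onset,
                               "offset": tactile_onset + sim.tactile_duration})
        t_end = tactile_onset + sim.post_window
        n_steps = int(round(t_end / sim.dt))
        onset_step = int(round(tactile_onset / sim.dt))

        if visual_stim is None:
            # nothing drives the network before touch: skip ahead, forgetting only
            self.idle(tactile_onset / 1000.0)
            start_step = onset_step
        else:
            start_step = 0

        n = c.grid.n_per_side
        zeros = np.zeros((n, n))
        trace = []
        for k in range(start_step, n_steps):
            t = k * sim.dt
            e_t = external_input(tact, c.grid, t, sim.rf_sigma_tactile) \
                if tact.onset <= t < tact.offset else zeros
            e_v = external_input(visual_stim, c.grid, t, sim.rf_sigma_visual) \
                if visual_stim is not None else zeros
            self.step(e_t, e_v, learn=learn)
            if k >= onset_step:
                trace.append(float(np.sum(self.z_tactile)))

        rt = decode_rt(np.asarray(trace), sim.p_th, sim.dt)
        dist = (visual_stim.distance_at(tactile_onset)
                if visual_stim is not None and visual_stim.start_distance is not None
                else np.nan)
        return {"network_rt": rt, "timeout": bool(np.isnan(rt)),
                "distance_cm": dist}


def build_network(config: NetworkConfig | None = None) -> PPSNetwork:
    """Assemble the network: basal weights, feedback maps, state at rest."""
    return PPSNetwork(config)


def session_schedule(distances_cm, velocity: float, n_reps: int = 20,
                     seed=None, include_unisensory: bool = True,
                     start_distance: float = 200.0) -> pd.DataFrame:
    """Seeded permuted trial schedule for a simulated session.

    One condition per visuo-tactile distance plus (optionally) a unisensory
    tactile condition, ``n_reps`` trials each, in a permutation fixed by
    ``seed`` so sweeps over network parameters can reuse the identical
    sequence.  Tactile onset for a distance D is the time the looming
    stimulus reaches D; unisensory trials draw their onset from the same
    set.
    """
    distances_cm = np.asarray(distances_cm, dtype=float)
    if np.any(distances_cm >= start_distance):
        raise ValueError("distances must be closer than the looming start")
    rng = np.random.default_rng(seed)
    onsets = (start_distance - distances_cm) / velocity * 1000.0  # ms
    rows = []
    for k, (d, on) in enumerate(zip(distances_cm, onsets), start=1):
        rows += [(k, d, on)] * n_reps
    if include_unisensory:
        uni_onsets = rng.choice(onsets, size=n_reps)
        rows += [(0, np.nan, on) for on in uni_onsets]
    df = pd.DataFrame(rows, columns=["condition", "distance_cm", "tactile_onset_ms"])
    df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


def run_session(network: PPSNetwork, schedule: pd.DataFrame | None = None,
                distances_cm=None, velocity: float = 75.0, n_reps: int = 20,
                seed=None, start_distance: float = 200.0) -> pd.DataFrame:
    """Run a whole simulated session, weights carried continuously.

    Either pass a prebuilt ``schedule`` (see :func:`session_schedule`) or
    the pieces to build one.  Between trials the configured stimulus-free
    gap elapses (forgetting only).  Returns one row per trial with the
    decoded RT in ms (NaN = timeout).
    """
    c = network.config
    if schedule is None:
        if distances_cm is None:
            raise ValueError("need either a schedule or distances_cm")
        schedule = session_schedule(distances_cm, velocity, n_reps=n_reps,
                                    seed=seed, start_distance=start_distance)
    records = []
    for row in schedule.itertuples(index=False):
        if row.condition == 0:
            vis = None
        else:
            vis = StimulusSpec(**{**c.visual_stimulus.__dict__,
                                  "start_distance": start_distance,
                                  "velocity": velocity, "onset": 0.0,
                                  "offset": row.tactile_onset_ms + c.sim.post_window})
        res = network.run_trial(vis, row.tactile_onset_ms)
        records.append({
            "trial_index": row.trial_index,
            "condition": row.condition,
            "modality": "T" if row.condition == 0 else "VT",
            "distance_index": np.nan if row.condition == 0 else int(row.condition),
            "distance_cm": row.distance_cm,
            "rt_ms": res["network_rt"],
            "timeout": res["timeout"],
            "tau_H": c.hebbian.tau_h,
            "velocity": velocity,
            "seed": seed if seed is not None else -1,
        })
        network.idle(c.sim.inter_trial_gap)
    out = pd.DataFrame(records).sort_values("trial_index").reset_index(drop=True)
    from ..psychophysics import split_by_history
    out["history_label"] = split_by_history(
        out.rename(columns={"rt_ms": "rt"}))["history_label"]
    return out
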