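"""Session-level analysis of simulated RTs and parameter sweeps.

A simulated session is analysed exactly like the behavioural data: RTs are
averaged by distance, the distance sigmoid is fitted pooled and separately
for trials preceded by a larger vs smaller disparity, and the central-point
difference (larger - smaller) is the model's rapid-recalibration index.
The sweeps rerun the identical permuted schedule while varying the
forgetting time constant tau_H or the looming velocity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..psychophysics import fit_sigmoid, recalibration_index, split_by_history
from .config import NetworkConfig, default_config
from .model import PPSNetwork, run_session, session_schedule

__all__ = [
    "EXP1_DISTANCES_CM",
    "analyze_session",
    "simulate_recalibration",
    "sweep_tau",
    "sweep_velocity",
]

# visuo-tactile disparities probed in the looming behavioural design (D1..D6, cm)
EXP1_DISTANCES_CM = (55.25, 79.25, 103.25, 127.25, 151.25, 175.25)


def analyze_session(rts: pd.DataFrame, flat_tol_ms: float = 10.0) -> dict:
    """Fit the distance sigmoid to a session, pooled and split by history.

    ``rts`` is a :func:`~perispace.network.model.run_session` table.  The
    history split conditions each trial on the preceding trial's disparity
    (equal/extreme/undefined-previous trials are excluded).  Returns pooled
    and per-split fits, the recalibration index Delta x_c in cm, the
    empirical distance effect (max - min mean RT across distances, ms) and
    a flat-PPS flag (distance effect below ``flat_tol_ms``).
    """
    labeled = split_by_history(rts.rename(columns={"rt_ms": "rt"}))
    vt = labeled[(labeled["modality"] == "VT") & np.isfinite(labeled["rt"])]
    if vt.empty:
        raise ValueError("no usable visuo-tactile trials")

    by_dist = vt.groupby("distance_cm")["rt"].mean()
    distance_effect = float(by_dist.max() - by_dist.min())

    pooled = fit_sigmoid(vt["distance_cm"], vt["rt"])
    fits = {"pooled": pooled}
    for label in ("smaller", "larger"):
        sub = vt[vt["history_label"] == label]
        if sub["distance_cm"].nunique() >= 3:
            # split curves only span the interior levels; anchoring their
            # asymptotes to the pooled fit keeps x_c identifiable there
            fits[label] = fit_sigmoid(sub["distance_cm"], sub["rt"],
                                      fix_asymptotes=(pooled.y_min, pooled.y_max))
    delta = (recalibration_index(fits["larger"], fits["smaller"])
             if "smaller" in fits and "larger" in fits else np.nan)

    uni = labeled[(labeled["modality"] == "T") & np.isfinite(labeled["rt"])]
    return {
        "fits": fits,
        "delta_xc_cm": delta,
        "distance_effect_ms": distance_effect,
        "flat_pps": distance_effect < flat_tol_ms,
        "mean_rt_by_distance": by_dist,
        "unisensory_mean_rt": float(uni["rt"].mean()) if len(uni) else np.nan,
        "n_timeouts": int(rts["timeout"].sum()),
    }


def simulate_recalibration(tau_h: float = 4.0, velocity: float = 75.0,
                           n_reps: int = 20, seed=None,
                           config: NetworkConfig | None = None,
                           distances_cm=EXP1_DISTANCES_CM,
                           schedule: pd.DataFrame | None = None) -> dict:
    """One full session at a given forgetting constant and looming velocity.

    Builds a fresh network (basal weights), runs the permuted session and
    returns the :func:`analyze_session` summary plus the raw RT table.
    """
    config = config or default_config()
    config = config.replace(hebbian=config.hebbian.__class__(
        **{**config.hebbian.__dict__, "tau_h": tau_h}))
    if schedule is None:
        schedule = session_schedule(distances_cm, velocity, n_reps=n_reps, seed=seed)
    net = PPSNetwork(config)
    rts = run_session(net, schedule=schedule, velocity=velocity, seed=seed)
    out = analyze_session(rts)
    out["rts"] = rts
    out["tau_h"] = tau_h
    out["velocity"] = velocity
    return out


def sweep_tau(tau_values, velocity: float = 75.0, n_reps: int = 20, seed=None,
              config: NetworkConfig | None = None,
              distances_cm=EXP1_DISTANCES_CM) -> pd.DataFrame:
    """Recalibration and PPS-shape summary across forgetting time constants.

    All tau_H values see the identical permuted schedule (fixed by
    ``seed``), since trial order influences the outcome.  Returns one row
    per tau_H with the central-point difference, pooled central point,
    distance effect and flat-PPS flag.
    """
    schedule = session_schedule(distances_cm, velocity, n_reps=n_reps, seed=seed)
    rows = []
    for tau in tau_values:
        res = simulate_recalibration(tau_h=tau, velocity=velocity, seed=seed,
                                     config=config, schedule=schedule)
        rows.append({
            "tau_h": tau,
            "delta_xc_cm": res["delta_xc_cm"],
            "xc_pooled_cm": res["fits"]["pooled"].x_c,
            "b_pooled": res["fits"]["pooled"].b,
            "distance_effect_ms": res["distance_effect_ms"],
            "flat_pps": res["flat_pps"],
            "n_timeouts": res["n_timeouts"],
        })
    return pd.DataFrame(rows)


def sweep_velocity(velocities=(25.0, 50.0, 75.0, 100.0), tau_h: float = 4.0,
                   n_reps: int = 20, seed=None,
                   config: NetworkConfig | None = None,
                   distances_cm=EXP1_DISTANCES_CM) -> pd.DataFrame:
    """Recalibration summary across looming velocities at fixed tau_H.

    The permutation of conditions is fixed by ``seed`` across velocities
    (onset times differ, trial order does not).
    """
    rows = []
    for v in velocities:
        schedule = session_schedule(distances_cm, v, n_reps=n_reps, seed=seed)
        res = simulate_recalibration(tau_h=tau_h, velocity=v, seed=seed,
                                     config=config, schedule=schedule)
        rows.append({
            "velocity": v,
            "delta_xc_cm": res["delta_xc_cm"],
            "xc_pooled_cm": res["fits"]["pooled"].x_c,
            "distance_effect_ms": res["distance_effect_ms"],
            "flat_pps": res["flat_pps"],
            "n_timeouts": res["n_timeouts"],
        })
    return pd.DataFrame(rows)
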