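"""Sigmoid psychometrics and trial-history analysis of visuo-tactile reaction times.

The central quantity is the sigmoidal dependence of tactile RT on
visuo-tactile distance,

    y(x) = (y_min + y_max * exp((x - x_c)/b)) / (1 + exp((x - x_c)/b)),

where ``x`` is distance oriented so that larger x = larger visuo-tactile
disparity = slower RT.  ``x_c`` (the central point) operationalises the
boundary of peri-personal space and ``b`` the shallowness of the near/far
transition (larger b = shallower).  Trials are additionally split by the
disparity of the immediately preceding trial ("T-1 smaller" vs "T-1
larger"); the difference between the two central points is the rapid
recalibration index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

import statsmodels.api as sm

__all__ = [
    "sigmoid_eval",
    "SigmoidFit",
    "SigmoidRegression",
    "fit_sigmoid",
    "split_by_history",
    "qc_filter",
    "recalibration_index",
    "history_split_fits",
    "nback_design",
    "NBackGammaGLM",
    "slope_recal_correlation",
]


def sigmoid_eval(x, y_min, y_max, x_c, b):
    """Evaluate the RT-by-distance sigmoid.

    Rises from ``y_min`` (x -> -inf) to ``y_max`` (x -> +inf) with midpoint
    ``(y_min + y_max)/2`` at ``x = x_c``; ``b > 0`` is the scale of the
    transition (larger b = shallower).
    """
    if b <= 0:
        raise ValueError("b must be positive")
    x = np.asarray(x, dtype=float)
    # expit is the overflow-safe form of e/(1+e)
    p = expit((x - x_c) / b)
    return y_min + (y_max - y_min) * p


@dataclass
class SigmoidFit:
    """Parameters and goodness of fit of the RT-by-distance sigmoid."""

    y_min: float
    y_max: float
    x_c: float
    b: float
    r2: float
    converged: bool = True

    def __call__(self, x):
        return sigmoid_eval(x, self.y_min, self.y_max, self.x_c, self.b)


class SigmoidRegression(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the RT-by-distance sigmoid.

    Parameters
    ----------
    aggregate : {"mean", "none"}
        With ``"mean"`` (default) trials are averaged per distance before
        fitting, so the fit criterion is on condition means.
    b_bounds : tuple of float
        Box bounds on the transition-scale parameter ``b``.
    xc_pad : float
        The central point is constrained to ``[x.min() - xc_pad * dx,
        x.max() + xc_pad * dx]`` where ``dx`` is the mean level spacing.

    Attributes
    ----------
    y_min_, y_max_, x_c_, b_ : float
        Fitted parameters.
    r2_ : float
        Coefficient of determination on the fitted means
        (``-inf`` if the optimiser failed).
    converged_ : bool
    """

    def __init__(self, aggregate="mean", b_bounds=(1e-3, 100.0), xc_pad=2.0,
                 fix_asymptotes=None):
        self.aggregate = aggregate
        self.b_bounds = b_bounds
        self.xc_pad = xc_pad
        self.fix_asymptotes = fix_asymptotes

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]

        if self.aggregate == "mean":
            xs = np.unique(x)
            ys = np.array([y[x == xi].mean() for xi in xs])
        elif self.aggregate == "none":
            order = np.argsort(x, kind="stable")
            xs, ys = x[order], y[order]
        else:
            raise ValueError(f"unknown aggregate={self.aggregate!r}")
        n_levels = np.unique(xs).size
        min_levels = 4 if self.fix_asymptotes is None else 3
        if n_levels < min_levels:
            raise ValueError(f"need at least {min_levels} distance levels with finite RT")

        dx = np.mean(np.diff(np.unique(xs))) if n_levels > 1 else 1.0
        lo_y, hi_y = float(ys.min()), float(ys.max())
        span = max(hi_y - lo_y, 1e-9)
        xc0 = float(0.5 * (xs.min() + xs.max()))
        xc_lo, xc_hi = xs.min() - self.xc_pad * dx, xs.max() + self.xc_pad * dx
        b_lo, b_hi = self.b_bounds[0] * dx, self.b_bounds[1] * dx
        if self.fix_asymptotes is None:
            p0 = [lo_y, hi_y, xc0, 1.0 * dx]
            bounds = ([lo_y - 2 * span, lo_y - 2 * span, xc_lo, b_lo],
                      [hi_y + 2 * span, hi_y + 2 * span, xc_hi, b_hi])

            def resid(p):
                return sigmoid_eval(xs, *p) - ys
        else:
            fy_min, fy_max = map(float, self.fix_asymptotes)
            p0 = [xc0, 1.0 * dx]
            bounds = ([xc_lo, b_lo], [xc_hi, b_hi])

            def resid(p):
                return sigmoid_eval(xs, fy_min, fy_max, *p) - ys

        try:
            sol = optimize.least_squares(resid, p0, bounds=bounds, method="trf")
            converged = bool(sol.success)
            p = sol.x
        except Exception:
            converged, p = False, p0

        res_final = resid(p)
        if self.fix_asymptotes is not None:
            p = [*self.fix_asymptotes, *p]
        self.y_min_, self.y_max_, self.x_c_, self.b_ = map(float, p)
        if converged:
            ss_res = float(np.sum(res_final ** 2))
            ss_tot = float(np.sum((ys - ys.mean()) ** 2))
            self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")
        else:
            self.r2_ = float("-inf")
        self.converged_ = converged
        return self

    def predict(self, X):
        return sigmoid_eval(np.asarray(X, dtype=float).reshape(-1),
                            self.y_min_, self.y_max_, self.x_c_, self.b_)

    def result_(self) -> SigmoidFit:
        return SigmoidFit(self.y_min_, self.y_max_, self.x_c_, self.b_,
                          self.r2_, self.converged_)


def fit_sigmoid(x, y, **kwargs) -> SigmoidFit:
    """Fit the RT-by-distance sigmoid to per-distance mean RTs.

    Thin wrapper over :class:`SigmoidRegression`; ``x`` may be distance
    indices or centimetres, ``y`` the matching RTs (trials or means).
    """
    return SigmoidRegression(**kwargs).fit(x, y).result_()


def split_by_history(trials: pd.DataFrame) -> pd.DataFrame:
    """Label each trial by the disparity of the immediately preceding trial.

    ``trials`` must be in session order and carry ``trial_index`` and
    ``distance_index`` columns (NaN/None distance for catch or unisensory
    trials in designs where they carry no disparity).  Returns a copy with a
    ``history_label`` column in {"smaller", "larger", "excluded"}:

    * smaller / larger -- previous trial's disparity was smaller / larger
      than the current one;
    * excluded -- previous disparity equal or undefined (catch), first trial,
      current trial has no disparity, or the current level is the extreme
      smallest/largest level present (no smaller/larger condition exists).
    """
    if "trial_index" in trials.columns:
        ti = trials["trial_index"].to_numpy()
        if np.any(np.diff(ti) <= 0):
            raise ValueError("trials must be sorted in ascending session order")
    out = trials.copy()
    d = pd.to_numeric(out["distance_index"], errors="coerce").to_numpy(dtype=float)
    prev = np.concatenate(([np.nan], d[:-1]))
    finite = d[np.isfinite(d)]
    lo = finite.min() if finite.size else np.nan
    hi = finite.max() if finite.size else np.nan

    labels = np.full(len(out), "excluded", dtype=object)
    valid = np.isfinite(d) & np.isfinite(prev) & (d != lo) & (d != hi)
    labels[valid & (prev < d)] = "smaller"
    labels[valid & (prev > d)] = "larger"
    # equal previous distance stays excluded
    labels[valid & (prev == d)] = "excluded"
    out["history_label"] = labels
    return out


def qc_filter(r2s: dict, r2_min: float = 0.50) -> bool:
    """Keep a subject only if every sigmoid fit meets the goodness criterion.

    ``r2s`` maps split name (e.g. pooled/smaller/larger) to the fit's R^2;
    flagged fits carry ``-inf`` and therefore fail.  Returns True to keep.
    """
    if not r2s:
        raise ValueError("no fits supplied")
    return all(np.isfinite(v) and v >= r2_min for v in r2s.values())


def recalibration_index(fit_larger: SigmoidFit, fit_smaller: SigmoidFit) -> float:
    """Rapid-recalibration index: x_c("T-1 larger") - x_c("T-1 smaller").

    Positive values mean the PPS boundary sits farther from the body after a
    trial probing a larger visuo-tactile disparity.
    """
    return float(fit_larger.x_c - fit_smaller.x_c)


def history_split_fits(trials: pd.DataFrame, x: str = "distance_index") -> dict:
    """Pooled and history-split sigmoid fits for one subject/session.

    Labels the trials by preceding disparity, fits the sigmoid pooled over
    all visuo-tactile trials, then refits the smaller/larger subsets with
    the asymptotes anchored to the pooled estimates — the split curves only
    span the interior distance levels, where free asymptotes leave the
    central point unidentifiable.  Returns ``{"pooled", "smaller",
    "larger", "delta_xc"}``.
    """
    lab = trials if "history_label" in trials.columns else split_by_history(trials)
    vt = lab[(lab["modality"] == "VT") & np.isfinite(
        pd.to_numeric(lab["rt"], errors="coerce"))]
    pooled = fit_sigmoid(vt[x], vt["rt"])
    out = {"pooled": pooled}
    for label in ("smaller", "larger"):
        sub = vt[vt["history_label"] == label]
        out[label] = fit_sigmoid(sub[x], sub["rt"],
                                 fix_asymptotes=(pooled.y_min, pooled.y_max))
    out["delta_xc"] = recalibration_index(out["larger"], out["smaller"])
    return out


def nback_design(trials: pd.DataFrame, n: int = 10):
    """Build the lagged design for the trial-history GLM.

    Predictors are the stimulus disparity at lags 0..n-1 (lag 0 = current
    trial); the response is the RT at the current trial.  Rows whose RT or
    any lagged disparity is missing are dropped.  Returns ``(X, y)`` as a
    DataFrame with columns ``lag0..lag{n-1}`` and a Series.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(trials):
        raise ValueError("n exceeds the session length")
    d = pd.to_numeric(trials["distance_index"], errors="coerce").to_numpy(dtype=float)
    rt = pd.to_numeric(trials["rt"], errors="coerce").to_numpy(dtype=float)
    cols = {f"lag{k}": np.concatenate((np.full(k, np.nan), d[: len(d) - k]))
            for k in range(n)}
    X = pd.DataFrame(cols)
    y = pd.Series(rt, name="rt")
    keep = np.isfinite(y.to_numpy()) & np.isfinite(X.to_numpy()).all(axis=1)
    X, y = X.loc[keep].reset_index(drop=True), y.loc[keep].reset_index(drop=True)
    ranks = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()])) if len(X) else 0
    X.attrs["full_rank"] = bool(ranks == n + 1)
    return X, y


class NBackGammaGLM(BaseEstimator):
    """Gamma GLM (canonical inverse link) of RT on disparity at lags 0..n-1.

    Estimates how far back trial history directly shapes the current RT.
    Fitting is delegated to statsmodels; the headline summary is the ratio of
    each lag's coefficient to the lag-0 coefficient (``effect_ratios_``),
    i.e. the size of the t-k influence relative to the current trial.
    """

    def __init__(self, n: int = 10):
        self.n = n

    def fit(self, trials: pd.DataFrame):
        X, y = nback_design(trials, self.n)
        if not X.attrs.get("full_rank", True):
            raise np.linalg.LinAlgError("rank-deficient lag design (constant disparity?)")
        exog = sm.add_constant(X.to_numpy())
        import warnings as _warnings
        with _warnings.catch_warnings():
            # the canonical inverse link draws a domain warning from statsmodels
            _warnings.simplefilter("ignore")
            model = sm.GLM(y.to_numpy(), exog, family=sm.families.Gamma())
            self.results_ = model.fit()
        coefs = self.results_.params[1:]
        self.coefs_ = pd.Series(coefs, index=X.columns)
        self.pvalues_ = pd.Series(self.results_.pvalues[1:], index=X.columns)
        self.effect_ratios_ = self.coefs_ / self.coefs_["lag0"]
        self.n_obs_ = len(y)
        return self


def slope_recal_correlation(delta_xc, b):
    """Pearson correlation between per-subject recalibration and sigmoid shallowness.

    ``delta_xc`` is each subject's central-point shift (T-1 larger minus
    smaller) and ``b`` their pooled transition-scale parameter.  Returns
    ``(r, r2, p)``; a positive r means shallower near/far gradients
    recalibrate more.
    """
    delta_xc = np.asarray(delta_xc, dtype=float)
    b = np.asarray(b, dtype=float)
    if delta_xc.shape != b.shape or delta_xc.ndim != 1:
        raise ValueError("delta_xc and b must be 1-D and the same length")
    if len(delta_xc) < 3:
        raise ValueError("need at least 3 subjects")
    r, p = stats.pearsonr(delta_xc, b)
    return float(r), float(r * r), float(p)
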