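"""Cell-cycle parameter estimators for labeling experiments.

Implements the standard cumulative-labeling and percentage-of-labeled-
mitoses (PLM) analyses for steady-state asynchronous populations:

* The **cumulative labeling index** LI(t) rises linearly and saturates at
  the growth fraction GF.  With T_plateau the time at which the plateau is
  reached and LI_0 the extrapolated intercept of the rising line, the cycle
  parameters follow from two identities::

      T_plateau = T_C - T_S          LI_0 = GF * T_S / T_C

  so that T_C = T_plateau * GF / (GF - LI_0) and T_S = T_C - T_plateau.
  :func:`fit_cumulative` fits the hinge (segmented) model
  ``LI(t) = min(LI_0 + b*t, GF)`` by least squares with a grid-searched and
  locally refined breakpoint, then inverts the identities.

* The **PLM curve** — the fraction of mitotic (PH3+) cells that are EdU+ as
  a function of exposure time — rises from 0 to a plateau; the time of
  half-maximal rise estimates the mean G2 duration.  For a deterministic
  cycle the true curve is ``clamp((t - T_G2)/T_M, 0, 1)`` whose half-max
  sits at T_G2 + T_M/2; following the field's convention the raw half-max
  abscissa is reported as the G2 estimate, and the T_M/2-corrected value is
  exposed alongside.

* The **mitotic index** equals GF * T_M / T_C at steady state.

Closed-form oracles (:func:`closed_form_li`, :func:`closed_form_plm`,
:func:`expected_mitotic_index`) give the exact deterministic-cycle
expectations and are the reference the simulator is validated against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popsim import CycleParams, LabelingObservation, observations_to_frame

__all__ = [
    "LabelingCurve",
    "CumulativeFit",
    "PLMFit",
    "labeling_index",
    "mitotic_index",
    "plm_curve",
    "fit_cumulative",
    "fit_plm",
    "closed_form_li",
    "closed_form_plm",
    "expected_mitotic_index",
    "compare_groups",
]


@dataclass(frozen=True)
class LabelingCurve:
    """Per-replicate labeling-index points over exposure time.

    ``points`` has columns ``time_h``, ``replicate``, ``li``.  ``grouping``
    records whether values are per-replicate or already pooled.
    """

    points: pd.DataFrame
    grouping: Literal["per_replicate", "pooled"] = "per_replicate"

    def summary(self) -> pd.DataFrame:
        """Per-time mean of per-replicate values with SEM (sd/sqrt(n), ddof=1)."""
        g = self.points.groupby("time_h")["li"]
        out = g.agg(mean="mean", n="size")
        out["sem"] = g.std(ddof=1) / np.sqrt(out["n"])
        return out.reset_index()


@dataclass(frozen=True)
class CumulativeFit:
    """Result of the cumulative-labeling hinge fit.

    When ``plateau_reached`` the identities ``t_plateau_hat = t_c_hat -
    t_s_hat`` and ``li0_hat = gf_hat * t_s_hat / t_c_hat`` hold exactly (they
    are how T_C and T_S are computed).  When the data show no plateau the
    cycle parameters are unidentifiable and are ``None``.
    """

    gf_hat: float | None
    li0_hat: float
    t_plateau_hat: float | None
    t_c_hat: float | None
    t_s_hat: float | None
    rss: float
    plateau_reached: bool


@dataclass(frozen=True)
class PLMFit:
    """Result of the PLM half-maximum fit.

    ``t_g2_hat`` is the raw half-maximum abscissa (the conventional G2
    estimate); ``t_g2_corrected_hat`` subtracts half the mitosis duration
    when one is supplied, since for a deterministic cycle the half-max sits
    at T_G2 + T_M/2.
    """

    t_g2_hat: float
    plateau_level: float
    fit_kind: Literal["logistic", "interpolation"]
    rss: float
    t_g2_corrected_hat: float | None = None


def _obs_frame(obs: Sequence[LabelingObservation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        df = obs
    else:
        df = observations_to_frame(list(obs))
    bad = df.index[df["n_scored"] <= 0]
    if len(bad):
        raise ValueError(f"n_scored must be > 0; offending row index {bad[0]}")
    return df


def labeling_index(obs: Sequence[LabelingObservation] | pd.DataFrame) -> LabelingCurve:
    """Per-replicate labeling index LI = n_edu_pos / n_scored."""
    df = _obs_frame(obs)
    pts = pd.DataFrame({
        "time_h": df["time_h"].to_numpy(float),
        "replicate": df["replicate"].to_numpy(int),
        "li": df["n_edu_pos"].to_numpy(float) / df["n_scored"].to_numpy(float),
    })
    return LabelingCurve(points=pts, grouping="per_replicate")


def mitotic_index(obs: Sequence[LabelingObservation] | pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged PH3+ fraction per time (columns time_h, mean, n, sem)."""
    df = _obs_frame(obs)
    pts = pd.DataFrame({
        "time_h": df["time_h"].to_numpy(float),
        "replicate": df["replicate"].to_numpy(int),
        "li": df["n_ph3_pos"].to_numpy(float) / df["n_scored"].to_numpy(float),
    })
    return LabelingCurve(points=pts).summary()


def plm_curve(obs: Sequence[LabelingObservation] | pd.DataFrame,
              pooled: bool = True) -> pd.DataFrame:
    """Labeled-mitosis fraction vs time (columns ``time_h``, ``plm``, ``n_mitoses``).

    Mitotic cells are scarce in a typical sample, so by default PH3+ counts
    are pooled across replicates before forming the fraction; times with no
    mitotic cell at all are dropped with a warning.
    """
    df = _obs_frame(obs)
    if pooled:
        g = df.groupby("time_h")[["n_double_pos", "n_ph3_pos"]].sum()
    else:
        g = df.set_index(["time_h", "replicate"])[["n_double_pos", "n_ph3_pos"]]
    empty = g.index[g["n_ph3_pos"] == 0]
    if len(empty):
        warnings.warn(f"no mitotic cells at time(s) {list(empty)}; dropped from PLM curve")
        g = g[g["n_ph3_pos"] > 0]
    out = pd.DataFrame({
        "time_h": g.index.get_level_values("time_h"),
        "plm": g["n_double_pos"].to_numpy(float) / g["n_ph3_pos"].to_numpy(float),
        "n_mitoses": g["n_ph3_pos"].to_numpy(int),
    }).reset_index(drop=True)
    return out


def _hinge_ls(t: np.ndarray, y: np.ndarray, tp: float, max_plateau: float,
              w: np.ndarray | None = None) -> tuple[float, float, float, float]:
    """(Weighted) least squares of y ~ a + b*min(t, tp) with the plateau
    a + b*tp constrained to <= max_plateau.

    Returns (a, b, plateau, rss); rss is the weighted residual sum.
    """
    x = np.minimum(t, tp)
    sw = np.ones_like(x) if w is None else np.sqrt(w)
    A = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    plateau = a + b * tp
    if plateau > max_plateau:
        # refit on the boundary: a = max_plateau - b*tp, single-parameter LS in b
        z = sw * (x - tp)
        denom = float(z @ z)
        b = float(z @ (sw * (y - max_plateau))) / denom if denom > 0 else 0.0
        a = max_plateau - b * tp
        plateau = max_plateau
    resid = sw * (y - (a + b * x))
    return a, b, plateau, float(resid @ resid)


def _hinge_search(t: np.ndarray, y: np.ndarray, max_gf: float, n_grid: int,
                  w: np.ndarray | None):
    """Breakpoint grid search + bounded refinement for the hinge model.

    Returns ``(a, b, plateau, tp, rss, a_line, b_line, rss_line)`` where the
    ``_line`` values describe the no-breakpoint straight-line fit.
    """
    tu = np.unique(t)
    a_l, b_l, _, rss_line = _hinge_ls(t, y, float(tu[-1]), np.inf, w)

    def rss_at(tp: float) -> float:
        return _hinge_ls(t, y, tp, max_gf, w)[3]

    grid = np.linspace(float(tu[0]), float(tu[-1]), n_grid + 2)[1:-1]
    rss_grid = np.array([rss_at(tp) for tp in grid])
    i = int(np.argmin(rss_grid))
    left = grid[max(i - 1, 0)]
    right = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(rss_at, bounds=(left, right), method="bounded",
                                   options={"xatol": 1e-10})
    tp_best, rss_best = float(res.x), float(res.fun)
    if rss_grid[i] < rss_best:
        tp_best, rss_best = float(grid[i]), float(rss_grid[i])
    a, b, plateau, rss_best = _hinge_ls(t, y, tp_best, max_gf, w)
    return a, b, plateau, tp_best, rss_best, a_l, b_l, rss_line


def fit_cumulative(curve: LabelingCurve, max_gf: float = 1.0,
                   pool_replicates: bool = False,
                   weighting: Literal["binomial", "none"] = "binomial",
                   n_grid: int = 512) -> CumulativeFit:
    """Fit the hinge model ``LI(t) = min(LI_0 + b t, GF)`` and invert for T_C, T_S.

    The replicate-mean LI per time is fitted by default (per-replicate
    scoring is how the data are produced); set ``pool_replicates`` to fit
    every per-replicate point instead.  The breakpoint is scanned on a fine
    grid between the observed times and refined by bounded scalar
    minimization, so noiseless hinge data are recovered to machine-level
    accuracy.  The plateau (GF) is constrained to ``(0, max_gf]``.

    ``weighting="binomial"`` (default) re-fits once with inverse
    binomial-variance weights ``1/(p(1-p))`` taken from the first pass's
    fitted values (clipped away from 0 and 1): labeling fractions near the
    extremes are measured more precisely than mid-range ones, and the
    reweighted fit uses that.  ``"none"`` keeps ordinary least squares.

    Raises ``ValueError`` for fewer than 3 distinct times or for a curve
    with no rising phase.
    """
    if pool_replicates:
        pts = curve.points
        t = pts["time_h"].to_numpy(float)
        y = pts["li"].to_numpy(float)
    else:
        s = curve.summary()
        t = s["time_h"].to_numpy(float)
        y = s["mean"].to_numpy(float)
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    tu = np.unique(t)
    if tu.size < 3:
        raise ValueError(f"need >= 3 distinct times to fit, got {tu.size}")
    if np.allclose(y, y[0]):
        raise ValueError("no rising phase: labeling index is constant")

    a, b, plateau, tp_best, rss_best, a_l, b_l, rss_line = _hinge_search(
        t, y, max_gf, n_grid, None)
    if weighting == "binomial" and b > 0:
        p_fit = np.clip(a + b * np.minimum(t, tp_best), 0.02, 0.98)
        w = 1.0 / (p_fit * (1.0 - p_fit))
        a, b, plateau, tp_best, rss_best, a_l, b_l, rss_line = _hinge_search(
            t, y, max_gf, n_grid, w)

    if b <= 0 and b_l <= 0:
        raise ValueError("no rising phase: fitted slope is not positive")

    improves = rss_best < (rss_line * (1 - 1e-9) if rss_line > 0 else 1e-18)
    if not improves or b <= 0:
        # no interior breakpoint improves on a straight line: plateau not reached
        if b_l <= 0:
            raise ValueError("no rising phase: fitted slope is not positive")
        return CumulativeFit(gf_hat=None, li0_hat=a_l, t_plateau_hat=None,
                             t_c_hat=None, t_s_hat=None, rss=rss_line,
                             plateau_reached=False)

    gf = plateau
    li0 = a
    t_plateau = (gf - li0) / b  # == tp_best by construction
    t_c = gf / b
    t_s = t_c - t_plateau
    return CumulativeFit(gf_hat=gf, li0_hat=li0, t_plateau_hat=t_plateau,
                         t_c_hat=t_c, t_s_hat=t_s, rss=rss_best,
                         plateau_reached=True)


def fit_plm(curve: pd.DataFrame, t_m: float | None = None,
            tol: float = 1e-8) -> PLMFit:
    """Estimate G2 duration from a labeled-mitosis-fraction curve.

    ``curve`` needs columns ``time_h`` and ``plm`` (fractions in [0, 1]).  A
    three-parameter logistic rising to a plateau is fitted by least squares;
    ``t_g2_hat`` is the half-plateau abscissa.  If the logistic fit fails to
    converge the monotone linear-interpolation crossing of the half-plateau
    level is used instead (``fit_kind`` records which path ran).

    Raises ``ValueError`` when fewer than 4 points are given or when the
    curve never rises above half of its maximum.
    """
    t = curve["time_h"].to_numpy(float)
    y = curve["plm"].to_numpy(float)
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    if t.size < 4:
        raise ValueError(f"need >= 4 time points for a PLM fit, got {t.size}")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("PLM values must be fractions in [0, 1]")

    ymax = float(y.max())
    half = ymax / 2.0
    if ymax <= 0 or not np.any(y > half):
        raise ValueError("half-maximum not bracketed: curve never exceeds half of its max")

    if y[0] >= half:
        warnings.warn("curve already at or above half-maximum at the first time point; "
                      "returning the boundary estimate t_g2_hat = first time")
        t50 = float(t[0])
        rss = float(((y - ymax) ** 2).sum())
        return PLMFit(t_g2_hat=t50, plateau_level=ymax, fit_kind="interpolation",
                      rss=rss, t_g2_corrected_hat=None if t_m is None else t50 - t_m / 2)

    # monotone interpolation crossing of the half-plateau level
    j = int(np.argmax(y >= half))
    t_cross = float(np.interp(half, [y[j - 1], y[j]], [t[j - 1], t[j]]))

    def logistic(tt, p, t50, s):
        return p / (1.0 + np.exp(-(tt - t50) / s))

    span = float(t[-1] - t[0])
    fit_kind: Literal["logistic", "interpolation"] = "logistic"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                logistic, t, y,
                p0=[max(ymax, 1e-3), t_cross, max(span / 10.0, 1e-2)],
                bounds=([1e-6, t[0], 1e-4], [1.0, t[-1], 10.0 * span]),
                ftol=tol, xtol=tol, maxfev=5000,
            )
        p_hat, t50, s_hat = (float(v) for v in popt)
        rss = float(((y - logistic(t, *popt)) ** 2).sum())
    except (RuntimeError, ValueError):
        fit_kind = "interpolation"
        p_hat, t50 = ymax, t_cross
        rss = float(((y - np.clip(np.interp(t, t, y), 0, 1)) ** 2).sum())
    return PLMFit(t_g2_hat=t50, plateau_level=p_hat, fit_kind=fit_kind, rss=rss,
                  t_g2_corrected_hat=None if t_m is None else t50 - t_m / 2)


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("exposure time t must be >= 0")
    return t


def closed_form_li(params: CycleParams, t) -> np.ndarray | float:
    """Exact cumulative labeling index for a deterministic cycle:
    ``GF * min((T_S + t)/T_C, 1)``."""
    t = _check_t(t)
    out = params.gf * np.minimum((params.t_s + t) / params.t_c, 1.0)
    return float(out) if out.ndim == 0 else out


def closed_form_plm(params: CycleParams, t) -> np.ndarray | float:
    """Exact labeled-mitosis fraction for a deterministic cycle:
    ``clamp((t - T_G2)/T_M, 0, 1)``."""
    t = _check_t(t)
    out = np.clip((t - params.t_g2) / params.t_m, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def expected_mitotic_index(params: CycleParams) -> float:
    """Steady-state mitotic fraction ``GF * T_M / T_C``."""
    return params.gf * params.t_m / params.t_c


def compare_groups(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Two-sample Welch t-test on per-replicate values (routine utility)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return {"t": float(res.statistic), "p_value": float(res.pvalue)}
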