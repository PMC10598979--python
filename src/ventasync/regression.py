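"""Piecewise-linear regression of PV half-cycles with F-ratio model-order selection.

A half-cycle is approximated by an r-segment piecewise linear model

    P(i) = k_sj * V(i) + P_bj + e(i)    for i in segment j,  j = 1..r,

where the slopes ``k_sj`` are local elastances (cmH2O/L), the intercepts
``P_bj`` are pressure-axis intercepts (cmH2O), and segments are contiguous
runs of samples in traversal order separated by breakpoints.  The residual
sum of squared errors (RSSE) is minimised by an exhaustive search over a
candidate breakpoint grid; the segment count r is chosen by a cascade of
hypothesis tests comparing r against r+1 segments through the ratio

    F(r+1 | r) = (RSSE_r - RSSE_{r+1}) / sigma^2,

with sigma^2 calibrated from breaths assumed free of asynchrony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy import stats

from .waveform import HalfCycle

__all__ = [
    "PiecewiseFit",
    "VarianceCalibration",
    "UnfittableError",
    "CalibrationError",
    "segment_cost",
    "fit_piecewise",
    "f_ratio",
    "critical_value",
    "select_model",
    "calibrate_variance",
]

SIGMA2_FLOOR = 1e-6  # cmH2O^2; avoids division blow-ups on noise-free synthetic data


class UnfittableError(ValueError):
    """Half-cycle has too few points for the requested segment count."""


class CalibrationError(ValueError):
    """Model-variance calibration is missing or invalid."""


@dataclass
class PiecewiseFit:
    """An r-segment piecewise linear fit of one PV half-cycle."""

    r: int
    breakpoints: np.ndarray            # volumes V at segment starts (r-1), traversal order
    breakpoint_pressures: np.ndarray   # fitted P at each breakpoint, cmH2O
    breakpoint_indices: np.ndarray     # sample index of each breakpoint within the half
    slopes: np.ndarray                 # k_s1..k_sr, cmH2O/L (nan where degenerate)
    intercepts: np.ndarray             # P_b1..P_br, cmH2O
    rsse: float                        # cmH2O^2
    n_points: int
    phase: str
    n_combinations: int = 1            # breakpoint combinations searched
    selection: dict | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "phase": self.phase,
            "breakpoints": [float(v) for v in self.breakpoints],
            "breakpoint_pressures": [float(v) for v in self.breakpoint_pressures],
            "slopes": [float(v) for v in self.slopes],
            "intercepts": [float(v) for v in self.intercepts],
            "rsse": float(self.rsse),
            "n_points": int(self.n_points),
        }


@dataclass(frozen=True)
class VarianceCalibration:
    """Model variance sigma^2 estimated from presumed non-asynchronous breaths."""

    sigma2: float           # cmH2O^2
    n_halves_used: int
    method: str             # "per-breath" | "rolling-mean" | "median"

    def __post_init__(self):
        if not (self.sigma2 > 0):
            raise CalibrationError("sigma2 must be positive")


def segment_cost(volume: np.ndarray, pressure: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of P on V for one segment.

    Returns ``(slope, intercept, sse)``.  If all volumes coincide (a vertical
    segment) the slope is undefined (nan), the intercept is the mean pressure
    and the SSE is taken against that mean.
    """
    v = np.asarray(volume, dtype=float)
    p = np.asarray(pressure, dtype=float)
    n = v.size
    if n < 2:
        raise UnfittableError("segment needs at least 2 points")
    vm, pm = v.mean(), p.mean()
    dv, dp = v - vm, p - pm
    svv = float(dv @ dv)
    scale = float(np.max(np.abs(v))) if n else 0.0
    if svv <= (1e-12 * max(scale, 1.0)) ** 2 * n:
        sse = float(dp @ dp)
        return math.nan, pm, sse
    slope = float(dv @ dp) / svv
    intercept = pm - slope * vm
    resid = dp - slope * dv
    sse = float(resid @ resid)
    return slope, intercept, max(sse, 0.0)


def _prefix_costs(v: np.ndarray, p: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """SSE of an OLS line over every slice [bounds[i], bounds[j]) with i < j.

    Fast raw-moment arithmetic via prefix sums; used only to *search* the
    breakpoint grid — the returned fit is re-evaluated stably per segment.
    """
    s1 = np.concatenate(([0.0], np.cumsum(np.ones_like(v))))
    sv = np.concatenate(([0.0], np.cumsum(v)))
    sp = np.concatenate(([0.0], np.cumsum(p)))
    svv = np.concatenate(([0.0], np.cumsum(v * v)))
    svp = np.concatenate(([0.0], np.cumsum(v * p)))
    spp = np.concatenate(([0.0], np.cumsum(p * p)))
    b = bounds
    nb = len(b)
    i = b[:, None]
    j = b[None, :]
    n = s1[j] - s1[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        dsv = sv[j] - sv[i]
        dsp = sp[j] - sp[i]
        svv_c = (svv[j] - svv[i]) - dsv * dsv / n
        svp_c = (svp[j] - svp[i]) - dsv * dsp / n
        spp_c = (spp[j] - spp[i]) - dsp * dsp / n
        vscale = max(float(np.max(np.abs(v))), 1.0)
        degenerate = svv_c <= (1e-12 * vscale) ** 2 * np.maximum(n, 1)
        cost = np.where(degenerate, spp_c, spp_c - np.where(degenerate, 0.0, svp_c) ** 2
                        / np.where(degenerate, 1.0, svv_c))
    cost = np.maximum(cost, 0.0)
    cost[np.tril_indices(nb)] = np.inf  # only i < j meaningful
    return cost


def _n_combinations(n: int, r: int, m: int) -> int:
    """Number of valid breakpoint combinations for r segments of >= m points."""
    return math.comb(max(n - r * m + r - 1, 0), r - 1)


def fit_piecewise(
    half: HalfCycle,
    r: int,
    min_segment_points: int = 5,
    max_candidates: int | None = None,
) -> PiecewiseFit:
    """Globally optimal r-segment fit by dynamic programming over breakpoints.

    Every sample index is a candidate breakpoint (optionally decimated to
    ``max_candidates`` evenly spaced candidates for very long half-cycles);
    segments must contain at least ``min_segment_points`` samples.  The DP
    over prefix segment costs is exactly equivalent to enumerating all valid
    breakpoint combinations; where combinations tie, the earliest breakpoints
    in traversal order win.
    """
    v, p = half.volume, half.pressure
    n = len(v)
    if r < 1:
        raise ValueError("r must be >= 1")
    if n < r * min_segment_points or n < 2 * r:
        raise UnfittableError(
            f"{n} points cannot support {r} segments of >= {min_segment_points} points"
        )

    if r == 1:
        slope, intercept, sse = segment_cost(v, p)
        return PiecewiseFit(
            r=1,
            breakpoints=np.empty(0),
            breakpoint_pressures=np.empty(0),
            breakpoint_indices=np.empty(0, dtype=int),
            slopes=np.array([slope]),
            intercepts=np.array([intercept]),
            rsse=sse,
            n_points=n,
            phase=half.phase,
        )

    m = min_segment_points
    interior = np.arange(1, n)
    if max_candidates is not None and len(interior) > max_candidates:
        interior = np.unique(np.round(
            np.linspace(1, n - 1, max_candidates)).astype(int))
    bounds = np.concatenate(([0], interior, [n]))
    cost = _prefix_costs(v, p, bounds)
    seg_len = bounds[None, :] - bounds[:, None]
    cost[seg_len < m] = np.inf

    nb = len(bounds)
    # best[j]: minimal cost of covering [0, bounds[j]) with the current number
    # of segments; argmin ties resolve to the smallest predecessor index.
    best = cost[0, :].copy()
    prev = np.zeros((r, nb), dtype=np.int64)
    for stage in range(1, r):
        tot = best[:, None] + cost
        nxt = np.min(tot, axis=0)
        prev[stage] = np.argmin(tot, axis=0)
        best = nxt
    if not np.isfinite(best[-1]):
        raise UnfittableError("no breakpoint combination satisfies the spacing constraint")

    chosen = [nb - 1]
    for stage in range(r - 1, 0, -1):
        chosen.append(int(prev[stage, chosen[-1]]))
    chosen.append(0)
    chosen_bounds = bounds[np.array(chosen[::-1])]

    slopes, intercepts, sses = [], [], []
    for a, b in zip(chosen_bounds[:-1], chosen_bounds[1:]):
        s, c, e = segment_cost(v[a:b], p[a:b])
        slopes.append(s)
        intercepts.append(c)
        sses.append(e)
    bp_idx = chosen_bounds[1:-1]
    bp_vol = v[bp_idx]
    bp_press = np.empty(len(bp_idx))
    for j, idx in enumerate(bp_idx):
        s, c = slopes[j + 1], intercepts[j + 1]
        bp_press[j] = c if math.isnan(s) else s * v[idx] + c

    return PiecewiseFit(
        r=r,
        breakpoints=bp_vol,
        breakpoint_pressures=bp_press,
        breakpoint_indices=np.asarray(bp_idx, dtype=int),
        slopes=np.array(slopes),
        intercepts=np.array(intercepts),
        rsse=float(math.fsum(sses)),
        n_points=n,
        phase=half.phase,
        n_combinations=(
            _n_combinations(n, r, m) if max_candidates is None
            else math.comb(len(interior), r - 1)
        ),
    )


def f_ratio(fit_r: PiecewiseFit, fit_r_plus_1: PiecewiseFit,
            calib: VarianceCalibration) -> float:
    """F(r+1 | r) = (RSSE_r - RSSE_{r+1}) / sigma^2, clamped at zero."""
    if fit_r_plus_1.r != fit_r.r + 1:
        raise ValueError("fits must differ by exactly one segment")
    if fit_r_plus_1.n_points != fit_r.n_points or fit_r_plus_1.phase != fit_r.phase:
        raise ValueError("fits must describe the same half-cycle")
    if calib.sigma2 <= 0:
        raise CalibrationError("sigma2 must be positive")
    return max(0.0, (fit_r.rsse - fit_r_plus_1.rsse) / calib.sigma2)


def critical_value(
    alpha: float,
    n_points: int,
    r: int,
    n_combinations: int = 1,
    method: str = "chi2-bonferroni",
    df_num: int = 2,
) -> float:
    """Critical value for the F(r+1 | r) cascade at significance ``alpha``.

    The default compares the RSSE improvement (in units of sigma^2) with a
    chi-square quantile Bonferroni-adjusted for the number of breakpoint
    combinations searched at the alternative: adding a segment adds two
    regression parameters whose location is optimised over the grid, so the
    improvement behaves as a maximum over correlated chi-square variates.
    ``method="f-quantile"`` instead uses the (df_num, N - 2(r+1)) F quantile
    without multiplicity adjustment.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if method == "chi2-bonferroni":
        a = alpha / max(int(n_combinations), 1)
        return float(stats.chi2.ppf(1.0 - a, df_num))
    if method == "f-quantile":
        dfd = max(n_points - 2 * (r + 1), 1)
        return float(stats.f.ppf(1.0 - alpha, df_num, dfd))
    raise ValueError(f"unknown critical value method {method!r}")


def select_model(
    half: HalfCycle,
    calib: VarianceCalibration,
    alpha: float = 0.01,
    r_max: int = 5,
    min_segment_points: int = 5,
    max_candidates: int | None = None,
    crit_method: str = "chi2-bonferroni",
) -> PiecewiseFit:
    """Choose the segment count by the nested F-test cascade.

    Starting from the two-segment model assumed for a normal half-cycle, the
    null of r segments is tested against r+1; the first acceptance (or
    reaching ``r_max`` / running out of points) stops the cascade.
    """
    if not 2 <= r_max <= 7:
        raise ValueError("r_max must lie in [2, 7]")
    fit = fit_piecewise(half, 2, min_segment_points, max_candidates)
    trace: list[dict] = []
    while fit.r < r_max:
        r_next = fit.r + 1
        if half.n_points < r_next * min_segment_points:
            break
        try:
            fit_next = fit_piecewise(half, r_next, min_segment_points, max_candidates)
        except UnfittableError:
            break
        f = f_ratio(fit, fit_next, calib)
        crit = critical_value(alpha, half.n_points, fit.r,
                              fit_next.n_combinations, crit_method)
        trace.append({"r": fit.r, "f": f, "critical": crit})
        if f < crit:
            break
        fit = fit_next
    fit.selection = {"alpha": alpha, "r_max": r_max, "sigma2": calib.sigma2,
                     "crit_method": crit_method, "tests": trace}
    return fit


def calibrate_variance(
    halves: list[HalfCycle],
    min_segment_points: int = 5,
    max_candidates: int | None = None,
    robust: str = "mean",
    floor: float = SIGMA2_FLOOR,
) -> VarianceCalibration:
    """Estimate sigma^2 from half-cycles assumed non-asynchronous.

    Each half contributes RSSE of its two-segment fit divided by N - 4
    (two slopes and two intercepts); the estimates are pooled by the mean
    (or median with ``robust="median"``) and floored at ``floor`` so that
    noise-free synthetic data cannot zero the denominator of the F-ratio.
    """
    if robust not in ("mean", "median"):
        raise ValueError("robust must be 'mean' or 'median'")
    per_half: list[float] = []
    for half in halves:
        n = half.n_points
        if n <= 4 or n < 2 * min_segment_points:
            continue
        try:
            fit = fit_piecewise(half, 2, min_segment_points, max_candidates)
        except UnfittableError:
            continue
        per_half.append(fit.rsse / (n - 4))
    if not per_half:
        raise CalibrationError("no fittable half-cycles for variance calibration")
    agg = float(np.mean(per_half) if robust == "mean" else np.median(per_half))
    return VarianceCalibration(
        sigma2=max(agg, floor),
        n_halves_used=len(per_half),
        method=robust if robust == "median" else "per-breath",
    )
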