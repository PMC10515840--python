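"""Fin-body coordination: robust fits of lift against upward rotation.

Larvae climb by combining trunk-driven rotation (which redirects thrust)
with pectoral-fin lift; the slope of lift vs upward rotation within a
speed bin quantifies how strongly the two effectors are coupled, and the
coupling steepens with swim speed.  Fits use iteratively reweighted least
squares with a Tukey bisquare weight (tuning constant 4.685 times the
scaled MAD of the residuals), which discounts gross outliers while
matching ordinary least squares on clean data.  Uncertainty comes from
resampling bouts with replacement (100 bootstrap refits); group
differences in fitted variables are scored by a paired two-tailed
bootstrap sign test floored at 1/n_boot.

Only bouts with positive upward rotation and positive lift enter the
fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import MAD_SCALE

__all__ = [
    "FinBodyFit",
    "robust_linear_fit",
    "fin_body_fit_by_bin",
    "bootstrap_fit_distribution",
    "bootstrap_difference_pvalue",
    "spearman_speed_ratio",
    "compare_correlations_fisher_z",
    "finfit_frame",
]

BISQUARE_C = 4.685
MIN_BOUTS_PER_BIN = 10
SPEED_BIN_NAMES = ("slow", "medium", "fast")


@dataclass
class FinBodyFit:
    speed_bin: str
    slope: float          # mm/deg
    intercept: float      # mm
    r_squared: float
    n_bouts: int
    reliable: bool = True
    bootstrap_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    bootstrap_r2: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> dict:
        out = {"speed_bin": self.speed_bin, "slope": self.slope,
               "intercept": self.intercept, "r_squared": self.r_squared,
               "n_bouts": self.n_bouts, "reliable": self.reliable}
        if self.bootstrap_slopes.size:
            q25, q50, q75 = np.percentile(self.bootstrap_slopes, [25, 50, 75])
            out.update(boot_slope_median=q50, boot_slope_q25=q25,
                       boot_slope_q75=q75)
        return out


def robust_linear_fit(x, y, max_iter: int = 50, tol: float = 1e-8):
    """Bisquare IRLS line fit; returns (slope, intercept, r_squared).

    Starts from ordinary least squares; at each iteration residuals are
    scaled by their scaled MAD and reweighted with the Tukey bisquare
    (w = (1 - u^2)^2 for |u| < 1, else 0, u = r / (4.685 * scale)).
    Iteration stops when coefficients change by less than ``tol``
    relatively.  R^2 is the squared weighted correlation between fitted
    and observed values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")

    def wls(w):
        W = np.sum(w)
        mx = np.sum(w * x) / W
        my = np.sum(w * y) / W
        sxx = np.sum(w * (x - mx) ** 2)
        if sxx == 0:
            raise ValueError("degenerate predictor under current weights")
        b = np.sum(w * (x - mx) * (y - my)) / sxx
        return b, my - b * mx

    slope, intercept = wls(np.ones_like(x))
    w = np.ones_like(x)
    for _ in range(max_iter):
        r = y - slope * x - intercept
        scale = MAD_SCALE * np.median(np.abs(r - np.median(r)))
        if scale == 0:  # exact fit (or degenerate residuals): done
            break
        u = r / (BISQUARE_C * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0 or np.count_nonzero(w) < 3:
            break
        new_slope, new_intercept = wls(w)
        denom = max(abs(slope), abs(intercept), 1e-12)
        done = (abs(new_slope - slope) < tol * denom
                and abs(new_intercept - intercept) < tol * denom)
        slope, intercept = new_slope, new_intercept
        if done:
            break

    fitted = slope * x + intercept
    W = w.sum()
    mf = np.sum(w * fitted) / W
    my = np.sum(w * y) / W
    cov = np.sum(w * (fitted - mf) * (y - my))
    vf = np.sum(w * (fitted - mf) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    r2 = float(cov**2 / (vf * vy)) if vf > 0 and vy > 0 else 1.0
    return float(slope), float(intercept), min(max(r2, 0.0), 1.0)


def _qualifying(bouts: pd.DataFrame) -> pd.DataFrame:
    """Bouts eligible for fin-body fits.

    Positive upward rotation and positive lift, restricted to
    climb-classified bouts when direction labels are present: coordination
    of trunk rotation with fin lift is the climbing mechanism, and dive
    bouts whose measured rotation is marginally positive carry only
    tracking noise.
    """
    q = bouts[(bouts.upward_rotation_deg > 0) & (bouts.lift_mm > 0)]
    if "direction" in q.columns:
        q = q[q.direction == "climb"]
    return q


def fin_body_fit_by_bin(bouts: pd.DataFrame) -> dict[str, FinBodyFit]:
    """One robust lift-vs-rotation fit per speed bin.

    ``bouts`` is a feature table with columns upward_rotation_deg, lift_mm,
    speed_bin.  Bins with fewer than 10 qualifying bouts are flagged
    unreliable and carry NaN coefficients.
    """
    q = _qualifying(bouts)
    fits = {}
    for name in SPEED_BIN_NAMES:
        sub = q[q.speed_bin == name]
        if len(sub) < MIN_BOUTS_PER_BIN:
            fits[name] = FinBodyFit(speed_bin=name, slope=np.nan,
                                    intercept=np.nan, r_squared=np.nan,
                                    n_bouts=len(sub), reliable=False)
            continue
        s, b, r2 = robust_linear_fit(sub.upward_rotation_deg.to_numpy(),
                                     sub.lift_mm.to_numpy())
        fits[name] = FinBodyFit(speed_bin=name, slope=s, intercept=b,
                                r_squared=r2, n_bouts=len(sub))
    return fits


def bootstrap_fit_distribution(bouts: pd.DataFrame, speed_bin: str,
                               n_boot: int = 100, seed: int = 0) -> FinBodyFit:
    """Point fit plus ``n_boot`` with-replacement refits for one speed bin."""
    sub = _qualifying(bouts)
    sub = sub[sub.speed_bin == speed_bin]
    if len(sub) < MIN_BOUTS_PER_BIN:
        return FinBodyFit(speed_bin=speed_bin, slope=np.nan, intercept=np.nan,
                          r_squared=np.nan, n_bouts=len(sub), reliable=False)
    x = sub.upward_rotation_deg.to_numpy()
    y = sub.lift_mm.to_numpy()
    s, b, r2 = robust_linear_fit(x, y)
    rng = np.random.default_rng(seed)
    bs = np.empty(n_boot)
    br = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        try:
            bs[i], _, br[i] = robust_linear_fit(x[idx], y[idx])
        except ValueError:  # resample collapsed onto one x value
            bs[i], br[i] = np.nan, np.nan
    return FinBodyFit(speed_bin=speed_bin, slope=s, intercept=b, r_squared=r2,
                      n_bouts=len(sub), bootstrap_slopes=bs, bootstrap_r2=br)


def bootstrap_difference_pvalue(ctrl_boot: np.ndarray, cond_boot: np.ndarray) -> float:
    """Paired two-tailed sign-fraction p for bootstrap distributions.

    Resample draws are paired by index; p = 2 * min(Pr(diff <= 0),
    Pr(diff >= 0)), floored at 1/n_boot.  Identical distributions give
    p = 1.
    """
    a = np.asarray(ctrl_boot, dtype=float)
    b = np.asarray(cond_boot, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("bootstrap arrays must be nonempty and equal length")
    d = b - a
    p = 2.0 * min(np.mean(d <= 0), np.mean(d >= 0))
    return float(min(max(p, 1.0 / a.size), 1.0))


def spearman_speed_ratio(bouts: pd.DataFrame):
    """Spearman correlation of lift/rotation ratio against peak speed.

    Uses qualifying bouts (positive rotation and lift); returns (rho, n).
    """
    q = _qualifying(bouts)
    if len(q) < 4:
        raise ValueError("need at least 4 qualifying bouts")
    ratio = q.lift_mm.to_numpy() / q.upward_rotation_deg.to_numpy()
    rho = sps.spearmanr(ratio, q.peak_speed_mms.to_numpy()).statistic
    return float(rho), int(len(q))


def compare_correlations_fisher_z(r1: float, n1: int, r2: float, n2: int):
    """Fisher z-test for the difference of two independent correlations."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def finfit_frame(fits: dict[str, FinBodyFit]) -> pd.DataFrame:
    return pd.DataFrame([f.summary() for f in fits.values()])
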