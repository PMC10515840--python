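"""Per-bout pitch-axis kinematic features.

Conventions (all relative to the moment of peak speed, t = 0):

* posture        -- pitch at -250 ms, the angle the fish holds just before
                    the bout; positive is nose-up.
* trajectory     -- atan2(v_z, |v_x|) at peak speed, in degrees; using the
                    absolute horizontal component makes climbs positive
                    regardless of left/right heading.
* climb / dive   -- trajectory > 0 / < 0; exactly 0 is left unclassified.
* upward rotation -- pitch change from -250 ms to the moment of peak
                    angular velocity (searched in -250..+250 ms on a
                    lightly smoothed pitch derivative).
* lift           -- residual depth change: observed dz over -100..+100 ms
                    minus |dx| * tan(posture at -100 ms), the depth change
                    thrust along the body axis would produce.  Positive
                    lift is attributed to the pectoral fins.
* speed bin      -- peak speed in [5, 7.5), [7.5, 15), [15, inf) mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bouts import Bout

__all__ = [
    "KinematicConfig",
    "posture_at",
    "trajectory_at_peak",
    "classify_direction",
    "upward_rotation",
    "compute_lift",
    "assign_speed_bin",
    "compute_features",
]

SPEED_BIN_EDGES = (5.0, 7.5, 15.0)
SPEED_BIN_NAMES = ("slow", "medium", "fast")


@dataclass
class KinematicConfig:
    posture_time: float = 0.250       # s before peak speed
    lift_window: float = 0.100        # s either side of peak
    angvel_search: tuple[float, float] = (-0.250, 0.250)  # s around peak
    angvel_smooth_frames: int = 7     # boxcar on the pitch derivative (~44 ms at 160 fps)
    speed_bin_edges: tuple[float, float, float] = SPEED_BIN_EDGES


def _sample_at(bout: Bout, t_rel: float, series: np.ndarray) -> float:
    """Value of a window series at t_peak + t_rel (linear interpolation)."""
    t = bout.window_time - bout.t_peak
    if t_rel < t[0] - 1e-9 or t_rel > t[-1] + 1e-9:
        raise ValueError("requested time outside the bout window")
    return float(np.interp(t_rel, t, series))


def posture_at(bout: Bout, cfg: KinematicConfig | None = None) -> float:
    """Pitch angle (deg) 250 ms before peak speed."""
    cfg = cfg or KinematicConfig()
    return _sample_at(bout, -cfg.posture_time, bout.window_pitch)


def trajectory_at_peak(bout: Bout) -> float:
    """Movement direction (deg) at peak speed; positive is upward."""
    mid = len(bout.window_time) // 2
    t = bout.window_time
    vx = np.gradient(bout.window_x, t)[mid]
    vz = np.gradient(bout.window_z, t)[mid]
    if vx == 0 and vz == 0:
        raise ValueError("zero velocity at peak speed")
    return float(np.degrees(np.arctan2(vz, abs(vx))))


def classify_direction(trajectory: float) -> str:
    if trajectory > 0:
        return "climb"
    if trajectory < 0:
        return "dive"
    return "undefined"


def upward_rotation(bout: Bout, cfg: KinematicConfig | None = None):
    """Pitch change (deg) from -250 ms to the peak of angular velocity.

    Returns (rotation, t_peak_angvel relative to peak speed).  The angular
    velocity is a centered difference smoothed with a short boxcar before
    the argmax, since the raw derivative is dominated by frame noise.
    """
    cfg = cfg or KinematicConfig()
    t = bout.window_time - bout.t_peak
    angvel = np.gradient(bout.window_pitch, bout.window_time)
    k = cfg.angvel_smooth_frames
    if k and k > 1:
        angvel = np.convolve(angvel, np.ones(k) / k, mode="same")
    lo, hi = cfg.angvel_search
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise ValueError("angular-velocity search window is empty")
    idx = np.flatnonzero(mask)
    vals = angvel[idx]
    # on a constant-velocity plateau the peak is ambiguous; take the latest
    # maximum so a monotone ramp contributes its full rotation
    ipk = idx[np.flatnonzero(vals >= vals.max() - 1e-12)[-1]]
    p0 = _sample_at(bout, -cfg.posture_time, bout.window_pitch)
    return float(bout.window_pitch[ipk] - p0), float(t[ipk])


def compute_lift(bout: Bout, cfg: KinematicConfig | None = None):
    """Residual depth change (mm) over the +/-100 ms window.

    Returns (lift, expected_dz) with lift = observed dz - expected_dz, so
    the two always sum to the observed depth change exactly.
    """
    cfg = cfg or KinematicConfig()
    w = cfg.lift_window
    pitch_pre = _sample_at(bout, -w, bout.window_pitch)
    if abs(pitch_pre) >= 90.0:
        raise ValueError("degenerate posture: |pitch(-100 ms)| >= 90 deg")
    dx = _sample_at(bout, +w, bout.window_x) - _sample_at(bout, -w, bout.window_x)
    dz = _sample_at(bout, +w, bout.window_z) - _sample_at(bout, -w, bout.window_z)
    expected = abs(dx) * np.tan(np.radians(pitch_pre))
    return float(dz - expected), float(expected)


def assign_speed_bin(peak_speed: float,
                     edges: tuple[float, float, float] = SPEED_BIN_EDGES) -> str:
    """Half-open speed bins on peak speed: [5,7.5) slow, [7.5,15) medium, >=15 fast."""
    lo, mid, hi = edges
    if peak_speed < lo:
        raise ValueError("peak speed below the bout threshold")
    if peak_speed < mid:
        return "slow"
    if peak_speed < hi:
        return "medium"
    return "fast"


def compute_features(bout: Bout, cfg: KinematicConfig | None = None) -> dict:
    """Fill the bout's feature dictionary in place and return it."""
    cfg = cfg or KinematicConfig()
    traj = trajectory_at_peak(bout)
    rot, t_av = upward_rotation(bout, cfg)
    lift, expected = compute_lift(bout, cfg)
    feats = {
        "posture_deg": posture_at(bout, cfg),
        "trajectory_deg": traj,
        "direction": classify_direction(traj),
        "upward_rotation_deg": rot,
        "t_peak_angvel_s": t_av,
        "lift_mm": lift,
        "expected_dz_mm": expected,
        "lift_rotation_ratio": lift / rot if rot != 0 else np.nan,
        "speed_bin": assign_speed_bin(bout.peak_speed, cfg.speed_bin_edges),
    }
    bout.features.update(feats)
    return feats
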