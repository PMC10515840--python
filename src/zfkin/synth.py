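"""Synthetic swim traces and calcium trial responses.

The generators are inverse models of the measurement definitions used by
the behavioral and imaging pipelines: every programmed quantity is chosen
so that, in the noiseless limit, the pipeline recovers it exactly (up to
frame discretization).  They are stand-ins with the statistical structure
the analysis assumes, not biomechanical simulations.

Swim bouts
----------
Bout peaks are placed by a renewal process (exponential inter-bout gap
plus a refractory period).  Each bout is built from three smooth pulses on
the frame grid:

* speed: a raised-cosine pulse of fixed duration whose maximum is the
  programmed peak speed, sampled uniformly within the bout's speed bin;
* pitch: a raised-cosine angular-velocity pulse during the acceleration
  phase, peaking 50 ms before peak speed; because the pulse is symmetric,
  the pitch change from -250 ms to the moment of peak angular velocity --
  the pipeline's "upward rotation" -- is exactly half the total pitch
  excursion, so a programmed rotation R is deposited as a 2R excursion;
* lift: a raised-cosine depth-rate pulse centred on peak speed and
  contained in the +/-100 ms lift window, with integral equal to the
  programmed lift L = intercept + slope(bin) * R + noise.

Horizontal and thrust-borne vertical velocity are solved so that total
speed matches the programmed pulse and the depth change decomposes
exactly into |dx| * tan(pitch at -100 ms) plus the deposited lift.  Pitch
between bouts is held constant, with short re-orientation ramps placed
midway through inter-bout gaps, outside every analysis window.

Ground truth is carried in a sidecar table keyed by bout index.

Tilt trials
-----------
Per-cell, per-trial scalar responses are Gaussian around a direction-
specific gain.  "Untuned" populations use nearly equal gains whose small
difference is invisible per cell but decodable when pooled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import SwimTrace
from .imaging import CellTrialResponses

__all__ = [
    "SwimSimParams",
    "CalciumSimParams",
    "SwimSimResult",
    "generate_swim_trace",
    "generate_cohort",
    "generate_tilt_trials",
]

SPEED_BIN_NAMES = ("slow", "medium", "fast")

# geometry of one bout, seconds relative to peak speed
ROT_CENTER = -0.050     # peak angular velocity precedes peak speed
ROT_HALF = 0.075        # rotation pulse half-width
LIFT_HALF = 0.075       # lift pulse half-width, inside the +/-100 ms window
EDGE_MARGIN = 0.300     # clearance from epoch edges around each peak
TRANSITION_HALF = 0.040 # half-width of between-bout re-orientation ramps


@dataclass
class SwimSimParams:
    """Free parameters of the swim-trace generator.

    Defaults emulate the 14-dpf fin-experiment control condition: bin
    weights follow the printed slow/medium/fast bout counts, fin-body
    slopes the printed control fits, and the climb fraction and posture
    scales the printed posture summaries.
    """

    fps: float = 160.0
    duration: float = 600.0            # s
    ibi_mean: float = 1.5              # s, exponential gap on top of refractory
    refractory: float = 0.3            # s
    bout_duration: float = 0.200       # s, full width of the speed pulse
    speed_bin_weights: tuple = (0.126, 0.426, 0.448)
    peak_speed_ranges: tuple = ((5.0, 7.5), (7.5, 15.0), (15.0, 25.0))  # mm/s
    climb_fraction: float = 0.58
    posture_mean_climb: float = 14.7   # deg
    posture_mean_dive: float = -16.6   # deg
    posture_sd: float = 10.0           # deg
    rotation_scale: float = 2.0        # deg, half-normal scale of pre-peak rotation
    finbody_slope_per_bin: tuple = (0.029, 0.041, 0.068)  # mm/deg
    lift_intercept: float = 0.15       # mm, rotation-independent fin lift
    lift_noise_sd: float = 0.05        # mm
    pitch_noise_sd: float = 0.1        # deg, i.i.d. per frame
    position_noise_sd: float = 0.0025  # mm, i.i.d. per frame on x and z
    seed: int = 0

    def __post_init__(self) -> None:
        if float(self.fps) not in (40.0, 160.0):
            raise ValueError("fps must be 40 or 160")
        for name in ("posture_sd", "lift_noise_sd", "pitch_noise_sd",
                     "position_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.speed_bin_weights) - 1.0) > 1e-9:
            raise ValueError("speed_bin_weights must sum to 1")
        bin_bounds = ((5.0, 7.5), (7.5, 15.0), (15.0, float("inf")))
        for (lo, hi), (blo, bhi) in zip(self.peak_speed_ranges, bin_bounds):
            if lo < blo - 1e-9 or hi > bhi + 1e-9 or lo >= hi:
                raise ValueError("peak_speed_ranges must respect bin edges 5/7.5/15")

    def to_json(self) -> str:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return json.dumps(d, default=list, indent=1)


@dataclass
class CalciumSimParams:
    n_cells: int = 13
    gain_up: float = 5.9       # expected response amplitude per trial
    gain_down: float = 5.0
    trial_noise_sd: float = 1.0
    n_trials_per_direction: int = 21
    protocol: str = "eccentric30"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_direction < 2:
            raise ValueError("need >= 2 trials per direction")
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be >= 0")


@dataclass
class SwimSimResult:
    trace: SwimTrace
    truth: pd.DataFrame       # one row per programmed bout
    params: SwimSimParams
    warnings: list = field(default_factory=list)

    def write(self, outdir, stem: str = "trace") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trace.to_frame().to_csv(outdir / f"{stem}.csv", index=False)
        self.truth.to_csv(outdir / f"{stem}_truth.csv", index=False)
        (outdir / f"{stem}_manifest.json").write_text(self.params.to_json())


def _rc_pulse(t: np.ndarray, center: float, half: float) -> np.ndarray:
    """Unit-peak raised cosine, zero outside |t - center| > half."""
    u = (t - center) / half
    out = np.zeros_like(t)
    m = np.abs(u) <= 1.0
    out[m] = 0.5 * (1.0 + np.cos(np.pi * u[m]))
    return out


def _rc_cdf(u) -> np.ndarray:
    """Integral fraction of the unit raised cosine up to u (clipped to [-1, 1])."""
    u = np.clip(u, -1.0, 1.0)
    return (u + 1.0) / 2.0 + np.sin(np.pi * u) / (2.0 * np.pi)


def generate_swim_trace(params: SwimSimParams) -> SwimSimResult:
    """Simulate one epoch of bout-based swimming with known ground truth."""
    rng = np.random.default_rng(params.seed)
    fps, dt = float(params.fps), 1.0 / float(params.fps)
    n = int(round(params.duration * fps)) + 1
    t = np.arange(n) * dt
    warns: list[str] = []

    # --- bout peak times (renewal process, snapped to the frame grid) ---
    peaks = []
    tp = EDGE_MARGIN + params.bout_duration / 2 + rng.exponential(params.ibi_mean)
    while tp + EDGE_MARGIN < params.duration:
        peaks.append(round(tp * fps) / fps)
        tp += (params.bout_duration + params.refractory
               + rng.exponential(params.ibi_mean))
    if not peaks:
        warns.append("duration too short for one bout; empty trace")
        empty = SwimTrace(time=t, x=np.zeros(n), z=np.zeros(n),
                          pitch=np.zeros(n), fps=fps)
        return SwimSimResult(trace=empty, truth=pd.DataFrame(), params=params,
                             warnings=warns)

    nb = len(peaks)
    peaks_arr = np.asarray(peaks)
    bins = rng.choice(3, size=nb, p=np.asarray(params.speed_bin_weights))
    lo = np.array([params.peak_speed_ranges[b][0] for b in bins])
    hi = np.array([params.peak_speed_ranges[b][1] for b in bins])
    peak_speed = rng.uniform(lo, hi)
    is_climb = rng.random(nb) < params.climb_fraction
    posture = np.where(
        is_climb,
        rng.normal(params.posture_mean_climb, params.posture_sd, nb),
        rng.normal(params.posture_mean_dive, params.posture_sd, nb))
    posture = np.clip(posture, -80.0, 80.0)
    rotation = np.abs(rng.normal(0.0, params.rotation_scale, nb))
    rotation = np.where(is_climb, rotation, -rotation)
    slopes = np.array([params.finbody_slope_per_bin[b] for b in bins])
    # fins generate lift on climbs; dives rely on axial thrust alone
    lift_noise = rng.normal(0.0, params.lift_noise_sd, nb)
    lift = np.where(is_climb,
                    params.lift_intercept + slopes * rotation + lift_noise,
                    lift_noise)

    # when the gap to the next bout is too short to fit a re-orientation
    # ramp outside both bouts' +/-250 ms analysis windows, the next bout
    # simply inherits the carried-over pitch
    MIN_REORIENT_GAP = 0.60
    has_transition = np.zeros(nb, dtype=bool)
    for k in range(nb - 1):
        if peaks[k + 1] - peaks[k] >= MIN_REORIENT_GAP:
            has_transition[k] = True
        else:
            posture[k + 1] = float(np.clip(posture[k] + 2.0 * rotation[k],
                                           -80.0, 80.0))

    # pitch at -100 ms follows from the programmed ramp geometry
    pitch_at_m100 = posture + 2.0 * rotation * float(
        _rc_cdf((-0.100 - ROT_CENTER) / ROT_HALF))

    def seg(lo_t, hi_t):
        """Index slice covering frame times in [lo_t, hi_t]."""
        return slice(max(int(np.ceil(lo_t * fps - 1e-9)), 0),
                     min(int(np.floor(hi_t * fps + 1e-9)) + 1, n))

    # --- per-frame series, assembled per bout on local slices ---
    speed = np.zeros(n)
    liftrate = np.zeros(n)
    tanphi = np.zeros(n)
    for k in range(nb):
        tp = peaks[k]
        sl = seg(tp - params.bout_duration / 2, tp + params.bout_duration / 2)
        speed[sl] += peak_speed[k] * _rc_pulse(t[sl], tp, params.bout_duration / 2)
        tanphi[sl] = math.tan(math.radians(pitch_at_m100[k]))
        sl = seg(tp - LIFT_HALF, tp + LIFT_HALF)
        liftrate[sl] += (lift[k] / LIFT_HALF) * _rc_pulse(t[sl], tp, LIFT_HALF)

    # pitch: piecewise -- hold posture, raised-cosine excursion of 2R during
    # the bout, hold posture + 2R, then re-orient midway through the gap
    pitch = np.empty(n)
    seg_start = 0.0
    for k in range(nb):
        tp = peaks[k]
        if k + 1 < nb:
            t_mid = (peaks[k] + peaks[k + 1]) / 2.0
            half = TRANSITION_HALF if has_transition[k] else 0.0
            seg_end = t_mid - half
        else:
            t_mid = None
            seg_end = params.duration
        sl = seg(seg_start, seg_end)
        pitch[sl] = posture[k] + 2.0 * rotation[k] * _rc_cdf(
            (t[sl] - (tp + ROT_CENTER)) / ROT_HALF)
        seg_start = seg_end
        if t_mid is not None and has_transition[k]:
            # linear re-orientation toward the next posture, mid-gap
            sl = seg(t_mid - TRANSITION_HALF, t_mid + TRANSITION_HALF)
            frac = (t[sl] - (t_mid - TRANSITION_HALF)) / (2.0 * TRANSITION_HALF)
            pitch[sl] = (posture[k] + 2.0 * rotation[k]) * (1 - frac) \
                + posture[k + 1] * frac
            seg_start = t_mid + TRANSITION_HALF

    # horizontal / vertical velocity: total speed preserved; depth change is
    # thrust projected through the -100 ms pitch plus the deposited lift
    s2 = speed**2
    disc = np.maximum(s2 * (1.0 + tanphi**2) - liftrate**2, 0.0)
    vx = (-tanphi * liftrate + np.sqrt(disc)) / (1.0 + tanphi**2)
    vx = np.where(speed > 0, vx, 0.0)
    vz = vx * tanphi + liftrate

    def _cumtrapz(v):
        return np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0 * dt)])

    x = _cumtrapz(vx)
    z = _cumtrapz(vz)

    if params.position_noise_sd > 0:
        x = x + rng.normal(0.0, params.position_noise_sd, n)
        z = z + rng.normal(0.0, params.position_noise_sd, n)
    if params.pitch_noise_sd > 0:
        pitch = pitch + rng.normal(0.0, params.pitch_noise_sd, n)
    pitch = np.clip(pitch, -179.999, 180.0)

    # programmed trajectory at peak speed, from the same velocity solution
    tphi = np.tan(np.radians(pitch_at_m100))
    l_pk = lift / LIFT_HALF
    disc_pk = np.maximum(peak_speed**2 * (1.0 + tphi**2) - l_pk**2, 0.0)
    vx_pk = (-tphi * l_pk + np.sqrt(disc_pk)) / (1.0 + tphi**2)
    traj = np.degrees(np.arctan2(vx_pk * tphi + l_pk, np.abs(vx_pk)))

    truth = pd.DataFrame({
        "bout_idx": np.arange(nb),
        "t_peak_s": peaks_arr,
        "peak_speed_mms": peak_speed,
        "speed_bin": [SPEED_BIN_NAMES[b] for b in bins],
        "programmed_climb": is_climb,
        "is_climb": traj > 0,
        "trajectory_deg": traj,
        "posture_deg": posture,
        "rotation_deg": rotation,
        "lift_mm": lift,
        "pitch_at_m100_deg": pitch_at_m100,
        "slope_mm_per_deg": slopes,
    })
    trace = SwimTrace(time=t, x=x, z=z, pitch=pitch, fps=fps)
    return SwimSimResult(trace=trace, truth=truth, params=params, warnings=warns)


def _apply_deltas(params: SwimSimParams, deltas: dict) -> SwimSimParams:
    """Offset numeric fields (tuples element-wise); used for condition groups."""
    kw = {}
    for key, d in deltas.items():
        cur = getattr(params, key)
        if isinstance(cur, tuple):
            kw[key] = tuple(c + dd for c, dd in zip(cur, d))
        else:
            kw[key] = cur + d
    return replace(params, **kw)


def generate_cohort(control: SwimSimParams, condition_deltas: dict,
                    n_repeats: int, seed: int = 0) -> list[dict]:
    """Paired control/condition simulations for ``n_repeats`` repeats.

    Each repeat draws independent sub-seeds; deltas are parameter offsets
    (e.g. ``{"posture_mean_climb": +4.3}`` or
    ``{"finbody_slope_per_bin": (-0.034, -0.06, -0.055)}``) emulating
    activation, lesion, or amputation effects.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for r, child in enumerate(ss.spawn(n_repeats)):
        s_ctrl, s_cond = (int(v) for v in child.generate_state(2) % (2**31))
        ctrl = generate_swim_trace(replace(control, seed=s_ctrl))
        cond_params = _apply_deltas(control, condition_deltas)
        cond = generate_swim_trace(replace(cond_params, seed=s_cond))
        out.append({"repeat_id": f"repeat{r}", "control": ctrl, "condition": cond})
    return out


def generate_tilt_trials(params: CalciumSimParams) -> list[CellTrialResponses]:
    """Per-cell trial response scalars r = gain(direction) + noise."""
    rng = np.random.default_rng(params.seed)
    cells = []
    nt = params.n_trials_per_direction
    for i in range(params.n_cells):
        up = params.gain_up + rng.normal(0.0, params.trial_noise_sd, nt)
        down = params.gain_down + rng.normal(0.0, params.trial_noise_sd, nt)
        cells.append(CellTrialResponses(
            cell_id=f"cell{i:03d}", responses_up=up, responses_down=down,
            protocol=params.protocol,
            meta={"gain_up": params.gain_up, "gain_down": params.gain_down}))
    return cells
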