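"""Swim-bout detection and repeat-level quality control.

Free-swimming larvae translate in discrete bouts separated by quiescent
inter-bout intervals.  A bout is a maximal run of frames whose speed
exceeds a threshold (default 5 mm/s); runs separated by sub-``merge_gap``
dips are merged.  Each bout is aligned at its moment of peak speed and
carries a fixed +/-250 ms window of position and pitch around that moment;
bouts whose window is truncated by the edge of a recording epoch are
dropped.  Bouts are excluded when the fish rotated more than 30 degrees
during the 250 ms acceleration phase (equivalently 120 deg/s), and repeats
with fewer than 650 bouts in either group are excluded outright, with the
remaining groups down-sampled to equal bout counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SwimTrace",
    "ExtractionConfig",
    "Bout",
    "RepeatDataset",
    "compute_speed",
    "segment_bouts",
    "apply_bout_exclusions",
    "filter_circadian_day",
    "qc_and_match_repeat",
    "extract_bouts",
]


@dataclass
class SwimTrace:
    """Per-frame trajectory of one recording epoch.

    time in seconds on a uniform grid, x (horizontal) and z (depth,
    positive up) in mm, pitch in degrees (positive nose-up).
    """

    time: np.ndarray
    x: np.ndarray
    z: np.ndarray
    pitch: np.ndarray
    fps: float
    epoch_id: str = "epoch0"
    light_on: np.ndarray | None = None  # per-frame day/night flag

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        n = self.time.size
        if not (self.x.size == self.z.size == self.pitch.size == n):
            raise ValueError("all series must share one length")
        if n >= 2:
            dt = np.diff(self.time)
            if dt.min() <= 0 or np.abs(dt - 1.0 / self.fps).max() > 1e-6:
                raise ValueError("time must increase uniformly at 1/fps")
        if n and (self.pitch.min() <= -180 or self.pitch.max() > 180):
            raise ValueError("pitch must lie in (-180, 180]")

    def __len__(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.time, "x_mm": self.x, "z_mm": self.z,
             "pitch_deg": self.pitch}
        d["epoch_id"] = self.epoch_id
        d["light_on"] = (np.ones(len(self), dtype=bool)
                         if self.light_on is None else self.light_on)
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fps: float) -> "SwimTrace":
        return cls(time=df["time_s"].to_numpy(), x=df["x_mm"].to_numpy(),
                   z=df["z_mm"].to_numpy(), pitch=df["pitch_deg"].to_numpy(),
                   fps=fps,
                   epoch_id=str(df["epoch_id"].iloc[0]) if "epoch_id" in df else "epoch0",
                   light_on=df["light_on"].to_numpy() if "light_on" in df else None)


@dataclass
class ExtractionConfig:
    speed_threshold: float = 5.0      # mm/s
    align_window: float = 0.250       # s either side of peak speed
    accel_rotation_limit: float = 30.0  # deg over the acceleration window
    min_bouts_per_repeat: int = 650
    merge_gap: float = 0.050          # s; shorter sub-threshold dips are bridged
    smooth_speed_frames: int = 0      # optional boxcar on speed, 0 = off

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be positive")
        if self.min_bouts_per_repeat < 1:
            raise ValueError("min_bouts_per_repeat must be >= 1")


@dataclass
class Bout:
    """One detected bout, aligned at peak speed.

    ``window_*`` slices span t_peak +/- align_window inclusive; feature
    slots are filled by the kinematics module.
    """

    t_peak: float
    peak_speed: float
    start: float
    end: float
    fps: float
    window_time: np.ndarray
    window_x: np.ndarray
    window_z: np.ndarray
    window_pitch: np.ndarray
    epoch_id: str = "epoch0"
    repeat_id: str = ""
    group_label: str = ""
    features: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RepeatDataset:
    """Paired control/condition bout collections for one experimental repeat."""

    repeat_id: str
    control_bouts: list
    condition_bouts: list
    qc_status: str = "pending"   # kept | excluded_low_count
    matched_n: int = 0


def compute_speed(trace: SwimTrace, smooth_frames: int = 0) -> np.ndarray:
    """Per-frame speed (mm/s) from central differences of x and z.

    Endpoints use one-sided differences.  ``smooth_frames`` applies an
    optional centered boxcar afterwards.
    """
    if len(trace) < 2:
        raise ValueError("insufficient frames to compute speed")
    vx = np.gradient(trace.x, trace.time)
    vz = np.gradient(trace.z, trace.time)
    speed = np.hypot(vx, vz)
    if smooth_frames and smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (inclusive) indices of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def segment_bouts(trace: SwimTrace, cfg: ExtractionConfig | None = None,
                  speed: np.ndarray | None = None) -> list[Bout]:
    """Detect bouts as supra-threshold speed runs aligned at peak speed.

    Runs separated by below-threshold gaps shorter than ``merge_gap`` are
    merged.  Bouts lacking the full alignment window are dropped.
    """
    cfg = cfg or ExtractionConfig()
    if speed is None:
        speed = compute_speed(trace, cfg.smooth_speed_frames)
    runs = _runs_above(speed > cfg.speed_threshold)
    if not runs:
        return []
    gap_frames = int(round(cfg.merge_gap * trace.fps))
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < gap_frames:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    half = int(round(cfg.align_window * trace.fps))
    bouts: list[Bout] = []
    n = len(trace)
    for s, e in merged:
        ipk = s + int(np.argmax(speed[s:e + 1]))
        if ipk - half < 0 or ipk + half >= n:
            continue  # truncated by epoch edge
        sl = slice(ipk - half, ipk + half + 1)
        bouts.append(Bout(
            t_peak=float(trace.time[ipk]),
            peak_speed=float(speed[ipk]),
            start=float(trace.time[s]),
            end=float(trace.time[e]),
            fps=trace.fps,
            window_time=trace.time[sl].copy(),
            window_x=trace.x[sl].copy(),
            window_z=trace.z[sl].copy(),
            window_pitch=trace.pitch[sl].copy(),
            epoch_id=trace.epoch_id,
        ))
    return bouts


def _accel_rotation(bout: Bout) -> float:
    """Pitch change over the acceleration window [t_peak - 250 ms, t_peak]."""
    mid = len(bout.window_pitch) // 2
    return float(bout.window_pitch[mid] - bout.window_pitch[0])


def apply_bout_exclusions(bouts: list[Bout], cfg: ExtractionConfig | None = None):
    """Drop bouts that rotated more than the limit during acceleration.

    Returns (kept bouts, exclusion log).  The speed criterion is enforced
    by construction during segmentation.
    """
    cfg = cfg or ExtractionConfig()
    kept, reasons = [], {"rotation": 0}
    for b in bouts:
        if abs(_accel_rotation(b)) > cfg.accel_rotation_limit:
            reasons["rotation"] += 1
        else:
            kept.append(b)
    n = len(bouts)
    log = {"n_input": n, "n_kept": len(kept), "reasons": reasons,
           "excluded_fraction": (n - len(kept)) / n if n else 0.0}
    return kept, log


def filter_circadian_day(bouts: list[Bout], schedule) -> list[Bout]:
    """Keep bouts whose peak falls inside a circadian-day interval.

    ``schedule`` is a sequence of (day_start_s, day_end_s) intervals.
    """
    if schedule is None:
        raise ValueError("a day/night schedule is required")
    intervals = list(schedule)
    return [b for b in bouts
            if any(lo <= b.t_peak < hi for lo, hi in intervals)]


def qc_and_match_repeat(repeat: RepeatDataset, cfg: ExtractionConfig | None = None,
                        seed: int = 0) -> RepeatDataset:
    """Apply the 650-bout repeat threshold, then match group sizes.

    The larger group is down-sampled without replacement using a seeded
    draw so reruns are identical.
    """
    cfg = cfg or ExtractionConfig()
    nc, nx = len(repeat.control_bouts), len(repeat.condition_bouts)
    if nc < cfg.min_bouts_per_repeat or nx < cfg.min_bouts_per_repeat:
        return replace(repeat, qc_status="excluded_low_count", matched_n=0)
    rng = np.random.default_rng(seed)
    m = min(nc, nx)
    ctrl, cond = list(repeat.control_bouts), list(repeat.condition_bouts)
    if nc > m:
        ctrl = [ctrl[i] for i in sorted(rng.choice(nc, size=m, replace=False))]
    if nx > m:
        cond = [cond[i] for i in sorted(rng.choice(nx, size=m, replace=False))]
    return replace(repeat, control_bouts=ctrl, condition_bouts=cond,
                   qc_status="kept", matched_n=m)


def extract_bouts(trace: SwimTrace, cfg: ExtractionConfig | None = None,
                  schedule=None):
    """Segment, day-filter, and exclusion-filter one trace.

    Convenience wrapper returning (kept bouts, exclusion log).
    """
    cfg = cfg or ExtractionConfig()
    bouts = segment_bouts(trace, cfg)
    if schedule is not None:
        bouts = filter_circadian_day(bouts, schedule)
    return apply_bout_exclusions(bouts, cfg)


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    """Flatten bouts (and any computed features) to one row per bout."""
    rows = []
    for b in bouts:
        row = {"epoch_id": b.epoch_id, "repeat_id": b.repeat_id,
               "group_label": b.group_label, "t_peak_s": b.t_peak,
               "peak_speed_mms": b.peak_speed, "start_s": b.start,
               "end_s": b.end, "duration_s": b.duration}
        row.update(b.features)
        rows.append(row)
    return pd.DataFrame(rows)
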