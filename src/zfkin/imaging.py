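"""Calcium-trace quantification for Purkinje-cell assays.

Two protocols are supported:

* ``eccentric30`` -- the fish is held at +/-30 deg for 15 s blocks; the
  per-trial scalar is the time-integral of dF/F over the stimulus, and the
  anesthetized recording at each eccentric angle provides the baseline.
* ``horizontal19`` -- the fish is tilted to +/-19 deg and rapidly returned
  to horizontal; the scalar is the maximum dF/F in the first second after
  return, against a 15 s pre-trial baseline.

Directional tuning is summarized by the directionality index
DI = (up - down) / (up + down) of the mean responses per direction; cells
with |DI| above 0.35 are classed as nose-up or nose-down tuned, the rest
as untuned.  For the chemogenetic-activation assay, a cell counts as
activated when its fluorescence ratio F/F0 exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTrace",
    "CellTrialResponses",
    "normalize_dff",
    "classify_activated",
    "trial_response_scalar",
    "directionality_index",
    "classify_tuning",
    "summarize_cell",
]

DI_THRESHOLD = 0.35
ACTIVATION_RATIO = 2.0
TIPM_VOLUME_RATE = 3.82  # volumes/s


@dataclass
class RoiTrace:
    cell_id: str
    fluorescence: np.ndarray     # arbitrary units per frame
    frame_rate: float
    fish_id: str = ""
    genotype_label: str = ""     # e.g. TRPV1+ / TRPV1-
    timepoint: str = ""          # pre, 3h, 6h, 9h, washout

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not np.all(np.isfinite(self.fluorescence)) or (self.fluorescence < 0).any():
            raise ValueError("fluorescence must be finite and non-negative")


@dataclass
class CellTrialResponses:
    """Per-trial scalar responses of one cell, split by tilt direction."""

    cell_id: str
    responses_up: np.ndarray
    responses_down: np.ndarray
    protocol: str = "eccentric30"   # eccentric30 | horizontal19
    fish_id: str = ""
    age_dpf: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses_up = np.asarray(self.responses_up, dtype=float)
        self.responses_down = np.asarray(self.responses_down, dtype=float)

    @property
    def response_up(self) -> float:
        return float(np.mean(self.responses_up))

    @property
    def response_down(self) -> float:
        return float(np.mean(self.responses_down))

    @property
    def di(self) -> float:
        up = max(self.response_up, 0.0)   # negative trial integrals clipped
        down = max(self.response_down, 0.0)
        return directionality_index(up, down)

    @property
    def tuning(self) -> str:
        return classify_tuning(self.di)


def normalize_dff(trace: RoiTrace, reference) -> np.ndarray:
    """F/F0 series against a scalar baseline or a (start, stop) frame window."""
    if np.ndim(reference) == 0:
        f0 = float(reference)
    else:
        lo, hi = reference
        f0 = float(np.mean(trace.fluorescence[int(lo):int(hi)]))
    if f0 <= 0:
        raise ValueError("baseline reference must be positive")
    return trace.fluorescence / f0


def classify_activated(ratio_series, threshold: float = ACTIVATION_RATIO,
                       on_dff: bool = False) -> bool:
    """Activation call for one cell at one timepoint.

    Default semantics: F/F0 > threshold.  ``on_dff=True`` instead tests
    dF/F0 = F/F0 - 1 against the threshold.
    """
    ratio = np.max(np.asarray(ratio_series, dtype=float))
    value = ratio - 1.0 if on_dff else ratio
    return bool(value > threshold)


def trial_response_scalar(trial_dff: np.ndarray, protocol: str,
                          frame_rate: float = TIPM_VOLUME_RATE,
                          stimulus_s: float = 15.0,
                          response_window_s: float = 1.0) -> float:
    """Collapse one trial's dF/F series to a scalar.

    eccentric30: integral of dF/F over the 15 s stimulus (dF/F * s).
    horizontal19: max dF/F within the first second after return; the series
    passed in must start at the moment of return.
    """
    y = np.asarray(trial_dff, dtype=float)
    t = np.arange(y.size) / frame_rate
    if protocol == "eccentric30":
        if t[-1] < stimulus_s:
            raise ValueError("trial shorter than the stimulus window")
        # integrate over exactly the stimulus window, interpolating the
        # final partial sampling interval
        grid = np.append(t[t < stimulus_s], stimulus_s)
        return float(np.trapezoid(np.interp(grid, t, y), grid))
    if protocol == "horizontal19":
        if t[-1] < response_window_s:
            raise ValueError("trial shorter than the response window")
        return float(np.max(y[t <= response_window_s]))
    raise ValueError(f"unknown protocol {protocol!r}")


def directionality_index(response_up: float, response_down: float) -> float:
    """(up - down) / (up + down); positive means nose-up preferring."""
    s = response_up + response_down
    if s == 0:
        raise ValueError("undefined DI: up + down responses sum to zero")
    return float((response_up - response_down) / s)


def classify_tuning(di: float, threshold: float = DI_THRESHOLD) -> str:
    """up / down / untuned partition on the directionality index.

    Strict inequalities: |DI| exactly at the threshold stays untuned.
    """
    if di > threshold:
        return "up"
    if di < -threshold:
        return "down"
    return "untuned"


def summarize_cell(cell: CellTrialResponses, threshold: float = DI_THRESHOLD) -> dict:
    return {
        "cell_id": cell.cell_id,
        "fish_id": cell.fish_id,
        "protocol": cell.protocol,
        "response_up": cell.response_up,
        "response_down": cell.response_down,
        "di": cell.di,
        "tuning": classify_tuning(cell.di, threshold),
    }
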