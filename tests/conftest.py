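import numpy as np
import pandas as pd
import pytest

from zfkin.bouts import extract_bouts
from zfkin.kinematics import compute_features
from zfkin.synth import SwimSimParams, generate_swim_trace


def featured_bouts(trace) -> pd.DataFrame:
    """Run extraction + kinematics on a trace; one row per kept bout."""
    kept, _ = extract_bouts(trace)
    rows = [compute_features(b) | {"t_peak_s": b.t_peak,
                                   "peak_speed_mms": b.peak_speed}
            for b in kept]
    return pd.DataFrame(rows)


def match_truth(measured: pd.DataFrame, truth: pd.DataFrame,
                tol_s: float = 0.02) -> pd.DataFrame:
    """Pair measured bouts with ground-truth rows by nearest peak time."""
    m = measured.sort_values("t_peak_s").reset_index(drop=True)
    t = truth.sort_values("t_peak_s").reset_index(drop=True)
    out = pd.merge_asof(m, t, on="t_peak_s", direction="nearest",
                        tolerance=tol_s, suffixes=("_m", "_t"))
    return out.dropna(subset=["bout_idx"])


@pytest.fixture(scope="session")
def noiseless_sim():
    params = SwimSimParams(duration=120.0, seed=7, pitch_noise_sd=0.0,
                           lift_noise_sd=0.0, position_noise_sd=0.0)
    return generate_swim_trace(params)


@pytest.fixture(scope="session")
def noisy_sim():
    return generate_swim_trace(SwimSimParams(duration=600.0, seed=11))


@pytest.fixture(scope="session")
def noisy_features(noisy_sim):
    return featured_bouts(noisy_sim.trace)


def single_pulse_trace(fps=160.0, peak=12.0, t_peak=1.0, duration=2.0,
                       width=0.2, pitch=0.0):
    """One raised-cosine speed pulse along x at constant pitch."""
    from zfkin.bouts import SwimTrace
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps
    u = (t - t_peak) / (width / 2)
    v = np.where(np.abs(u) <= 1, peak * 0.5 * (1 + np.cos(np.pi * u)), 0.0)
    x = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2 / fps)])
    return SwimTrace(time=t, x=x, z=np.zeros(n),
                     pitch=np.full(n, float(pitch)), fps=fps)
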