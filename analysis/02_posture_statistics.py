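"""Compare climb and dive postures between control and condition groups.

Reads the bout table from step 01 (regenerating it if absent), then runs
the full comparison machinery: bootstrap median CIs, two-sided rank-sum
p-values against the Šidák-corrected critical p, percent effect sizes,
and the dual significance rule (p below critical AND |effect| >= 15%).

Output: results/analysis/posture_comparisons.csv
"""

import importlib.util
from pathlib import Path

import pandas as pd

from zfkin.pipeline import analyze_posture, simulate_behavior

OUT = Path("results/analysis")


def _step01_config():
    spec = importlib.util.spec_from_file_location(
        "step01", Path(__file__).parent / "01_simulate_behavior.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod.config()


if __name__ == "__main__":
    cfg = _step01_config()
    bouts_path = OUT / "bouts.csv"
    if bouts_path.exists():
        bouts = pd.read_csv(bouts_path)
    else:
        bouts, _ = simulate_behavior(cfg)
    table = analyze_posture(bouts, cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "posture_comparisons.csv", index=False)
    for _, row in table.iterrows():
        star = "*" if row.significant else " "
        print(f"{row.measure:24s} {row.control_median:7.1f} vs "
              f"{row.condition_median:7.1f}  effect {row.effect_size_pct:+6.1f}%  "
              f"p={row.p_value:.3g} (crit {row.critical_p:.3g}) {star}")
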