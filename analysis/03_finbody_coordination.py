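"""Fin-body coordination: per-speed-bin robust fits and group contrasts.

For each speed bin (slow 5-7.5, medium 7.5-15, fast >15 mm/s) fits
lift against upward rotation with a bisquare robust line on qualifying
climb bouts, bootstraps the fit 100 times per group, computes the paired
bootstrap p-value for the slope difference and the effect size normalized
by the control fast-bin slope, and contrasts the speed-vs-lift/rotation
Spearman correlations with a Fisher z-test.

Output: results/analysis/finbody_report.json
"""

import importlib.util
import json
from pathlib import Path

import pandas as pd

from zfkin.pipeline import analyze_finbody, simulate_behavior, _jsonable

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
    report = analyze_finbody(bouts, cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "finbody_report.json").write_text(
        json.dumps(report, default=_jsonable, indent=1))
    for name, entry in report["bins"].items():
        c, x = entry["control"], entry["condition"]
        line = (f"slope {name:6s} control {c['slope']:+.4f} "
                f"vs condition {x['slope']:+.4f}")
        if "p_slope" in entry:
            line += (f"  p={entry['p_slope']:.3g}"
                     f"  effect {entry.get('effect_size_pct', float('nan')):+.0f}%")
        print(line)
    if "speed_ratio_correlation" in report:
        s = report["speed_ratio_correlation"]
        print(f"Spearman rho control {s['control_rho']:.3f} (n={s['control_n']}) "
              f"vs condition {s['condition_rho']:.3f} (n={s['condition_n']}), "
              f"Fisher z-test p={s['p']:.3g}")
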