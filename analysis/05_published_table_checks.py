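"""Worked-example checks against the published summary tables.

Recomputes every quantity derivable from printed values: effect sizes
from printed medians and slopes, Šidák critical p-values, Fisher exact
tests on the activated-cell tables, the Fisher z contrast of the printed
Spearman correlations, and the two-way ANOVA on the packaged per-repeat
IQR table (both the correct layout and the reference label alignment that
reproduces the published table).

Output: results/analysis/published_checks.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from zfkin.datasets import iqr_long_format, load_iqr_table, load_published_values
from zfkin.finbody import compare_correlations_fisher_z
from zfkin.stats import effect_size, fisher_exact_2x2, iqr_anova, sidak_critical

OUT = Path("results/analysis")

if __name__ == "__main__":
    pub = load_published_values()
    checks = {}

    eff = {}
    for exp, row in pub["climb_posture"].items():
        eff[f"climb_posture_{exp}"] = round(
            effect_size(row["control"], row["condition"]))
    for exp, block in pub["finbody_slopes"].items():
        for bin_ in ("slow", "medium", "fast"):
            eff[f"slope_{bin_}_{exp}"] = round(effect_size(
                block["control"][bin_], block["condition"][bin_],
                reference=block["reference"]))
    checks["effect_sizes_pct"] = eff

    checks["sidak_critical"] = {m: round(sidak_critical(0.05, m), 5)
                                for m in (8, 5, 12)}

    checks["fisher_exact"] = {
        name: round(fisher_exact_2x2(*rec["table"][0], *rec["table"][1]), 4)
        for name, rec in pub["fisher_tables"].items()}

    s = pub["spearman_speed_ratio"]
    z, p = compare_correlations_fisher_z(
        s["control"]["rho"], s["control"]["n_bouts"],
        s["lesion"]["rho"], s["lesion"]["n_bouts"])
    checks["spearman_contrast"] = {"z": round(z, 2), "p": float(p)}

    wide = load_iqr_table("activation_7dpf")
    correct = iqr_anova(iqr_long_format(wide))
    measures = [c for c in wide.columns if c != "group"]
    rows = []
    for g, sub in wide.groupby("group", sort=False):
        vals = sub[measures].to_numpy().T.ravel()
        labs = np.tile(measures, len(sub))
        rows += [{"group": g, "measure": m, "value": v}
                 for m, v in zip(labs, vals)]
    reference = iqr_anova(pd.DataFrame(rows))
    checks["iqr_anova"] = {
        "group_F_correct_layout": round(float(correct.row("group").F), 3),
        "group_F_reference_layout": round(float(reference.row("group").F), 3),
        "df": [float(correct.row(srz).df) for srz in
               ("group", "measure", "group:measure", "error", "total")],
    }

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "published_checks.json").write_text(json.dumps(checks, indent=1))
    print(json.dumps(checks, indent=1))
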