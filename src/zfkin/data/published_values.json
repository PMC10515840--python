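{
  "_comment": "Published summary values used as worked-example inputs and regression fixtures. Medians in the units shown; slopes in mm/deg; effects in percent.",
  "significance_rule": {"alpha": 0.05, "effect_floor_pct": 15},
  "sidak_families": {"activation_7dpf": 8, "lesion_7dpf": 8, "lesion_14dpf_behavior": 5, "finbody_14dpf": 12, "amputation_14dpf": 12},
  "critical_p_printed": {"m8": 0.006, "m5": 0.01, "m12": 0.004},
  "climb_posture": {
    "activation_7dpf": {"control": 14.7, "condition": 19.0, "effect_pct": 29},
    "lesion_7dpf": {"control": 10.0, "condition": 13.6, "effect_pct": 36},
    "lesion_14dpf": {"control": 14.3, "condition": 17.1, "effect_pct": 20}
  },
  "dive_posture": {
    "activation_7dpf": {"control": -16.6, "condition": -20.5, "effect_pct": 24},
    "lesion_7dpf": {"control": -11.7, "condition": -11.2, "effect_pct": -4},
    "lesion_14dpf": {"control": -9.8, "condition": -12.3, "effect_pct": 26}
  },
  "finbody_slopes": {
    "lesion_14dpf": {
      "control": {"slow": 0.029, "medium": 0.041, "fast": 0.068},
      "condition": {"slow": 0.033, "medium": 0.018, "fast": 0.026},
      "effect_pct": {"slow": 6, "medium": -34, "fast": -62},
      "reference": 0.068
    },
    "amputation_14dpf": {
      "control": {"slow": 0.036, "medium": 0.055, "fast": 0.068},
      "condition": {"slow": -0.005, "medium": -0.005, "fast": 0.013},
      "effect_pct": {"slow": -60, "medium": -88, "fast": -81},
      "reference": 0.068
    }
  },
  "spearman_speed_ratio": {
    "control": {"rho": 0.2193, "n_bouts": 11949},
    "lesion": {"rho": 0.0397, "n_bouts": 12132},
    "p_comparison": "<0.001"
  },
  "bout_counts_by_bin": {
    "amputation_experiment_control": {"slow": 1506, "medium": 5090, "fast": 5353},
    "amputation_experiment_lesion": {"slow": 1667, "medium": 6166, "fast": 4299},
    "amputation_experiment_amputated": {"slow": 1935, "medium": 6295, "fast": 4911}
  },
  "fisher_tables": {
    "activation_6h": {"table": [[0, 44], [8, 32]], "p": 0.0018},
    "washout": {"table": [[0, 22], [0, 22]], "p": 1.0}
  },
  "iqr_anova_reference": {
    "activation_7dpf": {
      "source": ["group", "measure", "group:measure", "error", "total"],
      "sum_sq": [65.0, 34.6, 80.3, 32818.0, 32998.0],
      "df": [3, 4, 12, 340, 359],
      "F": [0.225, 0.090, 0.069, null, null]
    }
  },
  "decoding_medians": {
    "pseudo_population": {"3": 0.78, "5": 0.88, "7": 1.0, "10": 1.0, "13": 1.0},
    "least_tuned": {"3": 0.67, "5": 0.86, "7": 0.88}
  },
  "tipm_counts": {"cells_total": 43, "cells_kept": 31, "tuned": 18, "untuned": 13, "trials_per_direction": 21}
}
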