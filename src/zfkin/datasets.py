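"""Packaged reference data: published summary values and per-repeat IQR tables."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["load_published_values", "load_iqr_table", "iqr_long_format"]

_IQR_FILES = {
    "activation_7dpf": "iqr_activation_7dpf.csv",
    "lesion_7dpf": "iqr_lesion_7dpf.csv",
    "lesion_14dpf": "iqr_lesion_14dpf.csv",
}

IQR_MEASURES = ("climb_posture", "dive_posture", "duration", "ibi", "speed")


def _data(name: str):
    return resources.files("zfkin").joinpath("data", name)


def load_published_values() -> dict:
    """Published medians, slopes, effect sizes and test results used as
    worked-example inputs and regression fixtures."""
    with _data("published_values.json").open() as fh:
        return json.load(fh)


def load_iqr_table(dataset: str = "activation_7dpf") -> pd.DataFrame:
    """Per-repeat interquartile ranges (wide format: one column per measure)."""
    if dataset not in _IQR_FILES:
        raise KeyError(f"unknown dataset {dataset!r}; choose from {sorted(_IQR_FILES)}")
    with _data(_IQR_FILES[dataset]).open() as fh:
        return pd.read_csv(fh)


def iqr_long_format(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide IQR table to (group, measure, value) rows for the ANOVA."""
    return wide.melt(id_vars="group", var_name="measure", value_name="value")
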