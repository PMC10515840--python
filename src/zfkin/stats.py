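"""Statistical layer shared by the behavioral and imaging analyses.

Implements the study-specific decision rules layered on top of standard
tests: rank-sum comparisons with Šidák-corrected critical p-values, a dual
significance criterion (p below the corrected threshold AND a relative
effect of at least 15%), scaled-MAD outlier flagging, bootstrap confidence
intervals for medians, a balanced two-way ANOVA on per-repeat interquartile
ranges, and Fisher's exact test for activated-cell counts.

Effect sizes are expressed in percent of a reference value (by default the
control median).  For fin-body slopes the reference is the control fast-bin
slope, the largest slope, so that near-zero control values in the slow bins
do not inflate the effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "ComparisonResult",
    "AnovaTable",
    "wilcoxon_rank_sum",
    "sidak_critical",
    "effect_size",
    "classify_significance",
    "bootstrap_median_ci",
    "mad_outliers",
    "iqr_anova",
    "fisher_exact_2x2",
    "compare_groups",
]

MAD_SCALE = 1.4826  # makes MAD consistent with the SD of a normal sample
EFFECT_FLOOR_PCT = 15.0


@dataclass
class ComparisonResult:
    """One control-vs-condition comparison of a scalar measure."""

    measure: str
    control_median: float
    control_ci: tuple[float, float]
    condition_median: float
    condition_ci: tuple[float, float]
    p_value: float
    critical_p: float
    effect_size_pct: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "control_median": self.control_median,
            "control_ci_lo": self.control_ci[0],
            "control_ci_hi": self.control_ci[1],
            "condition_median": self.condition_median,
            "condition_ci_lo": self.condition_ci[0],
            "condition_ci_hi": self.condition_ci[1],
            "p_value": self.p_value,
            "critical_p": self.critical_p,
            "effect_size_pct": self.effect_size_pct,
            "significant": self.significant,
        }


@dataclass
class AnovaTable:
    """Two-way fixed-effects ANOVA decomposition."""

    rows: pd.DataFrame  # source, sum_sq, df, mean_sq, F, p

    def __post_init__(self) -> None:
        comp = self.rows[self.rows.source != "total"]
        tot = self.rows.loc[self.rows.source == "total"]
        if len(tot):
            assert abs(comp.df.sum() - float(tot.df.iloc[0])) < 1e-9
            rel = abs(comp.sum_sq.sum() - float(tot.sum_sq.iloc[0]))
            assert rel <= 1e-6 * max(1.0, float(tot.sum_sq.iloc[0]))

    def row(self, source: str) -> pd.Series:
        return self.rows.set_index("source").loc[source]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have n <= 10 and no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= 10 and y.size <= 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                         use_continuity=True).pvalue
    )


def sidak_critical(alpha: float, m: int) -> float:
    """Per-comparison critical p controlling family-wise error over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def effect_size(control: float, condition: float, reference: float | None = None) -> float:
    """Percent change of condition relative to control, scaled by ``reference``.

    ``reference`` defaults to the control value; for fin-body slopes pass the
    control fast-bin slope.
    """
    if reference is None:
        reference = control
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (condition - control) / reference


def classify_significance(p: float, critical_p: float, effect_pct: float,
                          floor: float = EFFECT_FLOOR_PCT) -> bool:
    """Dual criterion: p below the corrected threshold and |effect| >= floor.

    The effect size is evaluated unrounded.
    """
    return bool(p < critical_p and abs(effect_pct) >= floor)


def bootstrap_median_ci(x, n_boot: int = 1000, level: float = 95.0,
                        seed: int | np.random.Generator = 0):
    """Percentile bootstrap CI of the median; returns (median, lo, hi)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(meds, [half, 100.0 - half])
    return float(np.median(x)), float(lo), float(hi)


def mad_outliers(x, k: float = 3.0, c: float = MAD_SCALE) -> np.ndarray:
    """Boolean mask of points deviating more than k scaled MADs from the median.

    If the MAD is zero, any point differing from the median is flagged.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) > k * c * mad


def iqr_anova(table: pd.DataFrame, value: str = "value",
              factor_a: str = "group", factor_b: str = "measure") -> AnovaTable:
    """Two-way fixed-effects ANOVA with interaction on a long-format table.

    Used to check whether per-repeat interquartile ranges vary enough across
    experimental groups to preclude pooling.  Type I sums of squares; the
    design here is balanced so the decomposition is unique.
    """
    df = table.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    counts = df.groupby(["_a", "_b"]).size()
    if (counts == 0).any() or counts.size < len(df["_a"].unique()) * len(df["_b"].unique()):
        raise ValueError("every factor cell needs at least one replicate")
    fit = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=1)
    rows = []
    name_map = {"C(_a)": factor_a, "C(_b)": factor_b,
                "C(_a):C(_b)": f"{factor_a}:{factor_b}", "Residual": "error"}
    for src, r in aov.iterrows():
        rows.append({
            "source": name_map[src],
            "sum_sq": float(r.sum_sq),
            "df": float(r.df),
            "mean_sq": float(r.sum_sq / r.df),
            "F": float(r.F) if np.isfinite(r.F) else np.nan,
            "p": float(r["PR(>F)"]) if np.isfinite(r["PR(>F)"]) else np.nan,
        })
    rows.append({
        "source": "total",
        "sum_sq": float(aov.sum_sq.sum()),
        "df": float(aov.df.sum()),
        "mean_sq": np.nan, "F": np.nan, "p": np.nan,
    })
    return AnovaTable(rows=pd.DataFrame(rows))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided rule: sum hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_groups(control, condition, measure: str, critical_p: float,
                   reference: float | None = None, n_boot: int = 1000,
                   seed: int = 0) -> ComparisonResult:
    """Full comparison of one measure: medians with bootstrap CIs, rank-sum
    p, percent effect, and the dual significance call."""
    cm, clo, chi = bootstrap_median_ci(control, n_boot=n_boot, seed=seed)
    xm, xlo, xhi = bootstrap_median_ci(condition, n_boot=n_boot, seed=seed + 1)
    p = wilcoxon_rank_sum(control, condition)
    eff = effect_size(cm, xm, reference=reference)
    return ComparisonResult(
        measure=measure,
        control_median=cm, control_ci=(clo, chi),
        condition_median=xm, condition_ci=(xlo, xhi),
        p_value=p, critical_p=critical_p,
        effect_size_pct=eff,
        significant=classify_significance(p, critical_p, eff),
    )
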