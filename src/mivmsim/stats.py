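"""Statistics for oocyte outcome tables and fluorescence quantification.

Categorical outcomes (nuclear chromatin configuration, mitochondria
distribution pattern) are compared against the control group with uncorrected
Pearson chi-square tests on category-versus-rest 2x2 collapses, graded with
the conventional thresholds (p < 0.05 / 0.01 / 0.001).  Per-oocyte
fluorescence intensities (arbitrary densitometric units, 0-255) are compared
by one-way ANOVA followed by Dunnett's many-to-one test against the control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MivmError

GRADE_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class SignificanceGrade:
    """A p-value with its conventional star grade."""

    p_value: float
    grade: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "grade", grade_of(self.p_value))


def grade_of(p: float) -> str:
    for thr, g in GRADE_THRESHOLDS:
        if p < thr:
            return g
    return "ns"


@dataclass
class OutcomeTable:
    """Counts of oocytes per category per experimental group."""

    groups: list[str]
    categories: list[str]
    counts: np.ndarray  # (n_groups, n_categories) non-negative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.groups), len(self.categories)):
            raise MivmError("counts shape does not match group/category labels")
        if np.any(self.counts < 0):
            raise MivmError("counts must be non-negative")

    @property
    def n_evaluated(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, group: str) -> np.ndarray:
        return self.counts[self.groups.index(group)]

    def percents(self) -> pd.DataFrame:
        """Integer percentages per cell, rounded half-up (the tables' convention)."""
        n = self.n_evaluated
        pct = np.array([
            [percent_report(c, nt) for c in row] for row, nt in zip(self.counts, n)
        ])
        return pd.DataFrame(pct, index=self.groups, columns=self.categories)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.groups, columns=self.categories)


@dataclass
class FluorescenceSample:
    """Per-oocyte fluorescence intensities for one group and one measure."""

    group: str
    values: np.ndarray      # ADU on the 0-255 pixel scale (or [0,1] for colocalization)
    measure: str = "mito_activity"  # mito_activity | ros_level | colocalization

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.measure == "colocalization":
            lo, hi = 0.0, 1.0
        else:
            lo, hi = 0.0, 255.0
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise MivmError(f"{self.measure} values outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int, corrected: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) for the 2x2 table [[a, b], [c, d]].

    Uncorrected by default; ``corrected=True`` applies the Yates continuity
    correction.  Raises on a zero margin (the test is undefined there).
    """
    if min(a, b, c, d) < 0:
        raise MivmError("counts must be non-negative")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        raise MivmError("chi-square undefined: a row or column margin is zero")
    det = abs(a * d - b * c)
    if corrected:
        det = max(0.0, det - n / 2.0)
    stat = n * det * det / math.prod(margins)
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def percent_report(count: int, n: int) -> int:
    """Integer percentage, rounded half-up (e.g. 31/59 -> 53, 27/72 -> 38)."""
    if n <= 0:
        raise MivmError("percent undefined for n <= 0")
    if not 0 <= count <= n:
        raise MivmError("count must lie in [0, n]")
    return int(math.floor(100.0 * count / n + 0.5))


def grade_table(
    table: OutcomeTable, control_group: str, corrected: bool = False,
    pooling: str = "category_vs_rest",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell significance of each group against the control.

    For every non-control group and every category, the table is collapsed to
    a 2x2 (this category vs all others, control vs group) and tested by
    Pearson chi-square.  Returns ``(grades, p_values)`` data frames indexed by
    the non-control groups.  ``pooling='full_table'`` instead runs a single
    omnibus test per group across all categories and assigns its grade to
    every cell (an alternative reading of per-row superscripts).
    """
    if control_group not in table.groups:
        raise MivmError(f"control group {control_group!r} not in table")
    ctrl = table.row(control_group)
    n_ctrl = ctrl.sum()
    others = [g for g in table.groups if g != control_group]
    grades = pd.DataFrame(index=others, columns=table.categories, dtype=object)
    pvals = pd.DataFrame(index=others, columns=table.categories, dtype=float)
    for g in others:
        row = table.row(g)
        n_g = row.sum()
        if pooling == "full_table":
            stat, p = sps.chi2_contingency(np.vstack([ctrl, row]), correction=corrected)[:2]
            grades.loc[g] = grade_of(p)
            pvals.loc[g] = p
            continue
        if pooling != "category_vs_rest":
            raise MivmError(f"unknown pooling {pooling!r}")
        for k, cat in enumerate(table.categories):
            _, p = chi_square_2x2(
                int(ctrl[k]), int(n_ctrl - ctrl[k]), int(row[k]), int(n_g - row[k]),
                corrected=corrected,
            )
            grades.loc[g, cat] = grade_of(p)
            pvals.loc[g, cat] = p
    return grades, pvals


def anova_dunnett(
    samples: list[FluorescenceSample], control_group: str
) -> dict:
    """One-way ANOVA plus Dunnett's many-to-one comparison against the control.

    Returns ``{"anova_F", "anova_p", "dunnett": {group: p}}``.  Requires at
    least two groups with at least two values each and non-degenerate
    within-group variance.
    """
    groups = {s.group: np.asarray(s.values, float) for s in samples}
    if control_group not in groups:
        raise MivmError(f"control group {control_group!r} missing")
    if len(groups) < 2:
        raise MivmError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise MivmError(f"group {g!r} has fewer than two values")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0 or all(np.var(v) == 0 for v in groups.values()):
        raise MivmError("degenerate (zero-variance) samples")
    control = groups[control_group]
    treat_names = [g for g in groups if g != control_group]
    treatments = [groups[g] for g in treat_names]
    F, p = sps.f_oneway(*groups.values())
    res = sps.dunnett(*treatments, control=control)
    return {
        "anova_F": float(F),
        "anova_p": float(p),
        "dunnett": {g: float(pv) for g, pv in zip(treat_names, res.pvalue)},
    }


def overlap_coefficient(signal_a, signal_b) -> float:
    """Manders overlap coefficient sum(ab) / sqrt(sum(a^2) sum(b^2)), in [0, 1].

    The standard colocalization measure between two non-negative fluorescence
    intensity signals (here: mitochondrial probe vs ROS probe).
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape:
        raise MivmError("signals must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise MivmError("signals must be non-negative")
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise MivmError("overlap undefined: a signal is identically zero")
    return float((a * b).sum() / denom)
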