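"""Summary statistics and significance tests for motility/force measurements.

All quantities are reported as mean ± SEM per condition group. Group
differences use the unequal-variance (Welch) two-sample t-test, two-sided.
Samples are screened for normality with a chi-square goodness-of-fit test
against the fitted normal before t-testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "summarize",
    "compare_groups",
    "normality_check",
    "summary_table",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float  # NaN (flagged) at n = 1
    unit: str

    @property
    def sem_defined(self) -> bool:
        return not np.isnan(self.sem)

    def __str__(self) -> str:
        if self.sem_defined:
            return f"{self.label}: {self.mean:.3g} ± {self.sem:.2g} {self.unit} (n={self.n})"
        return f"{self.label}: {self.mean:.3g} {self.unit} (n={self.n}, SEM undefined)"


def summarize(values, label: str = "", unit: str = "") -> GroupSummary:
    """Mean ± SEM of a measurement group; SEM = sample sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
    return GroupSummary(label=label, n=int(v.size), mean=float(v.mean()), sem=sem, unit=unit)


def compare_groups(a, b, *, paired: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (unequal variance) form by default.

    Returns (t statistic, p-value). A paired test is available for repeated
    measurements on the same growth cone.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    if paired:
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def normality_check(values, bins: int | None = None) -> tuple[float, float]:
    """Chi-square goodness of fit of a sample against its fitted normal.

    Observed counts fall into ``bins`` equal-probability bins of the fitted
    N(mean, sd); the statistic is referred to chi-square with dof = bins − 3
    (two estimated parameters). ``bins`` defaults to the Sturges rule.
    Requires n ≥ 20 and a non-degenerate sample.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError("insufficient n: normality check requires n >= 20")
    mu = v.mean()
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    if bins is None:
        bins = int(np.ceil(np.log2(v.size))) + 1
    if bins < 4:
        raise ValueError("need at least 4 bins for dof = bins - 3 >= 1")
    edges = sps.norm.ppf(np.linspace(0, 1, bins + 1), loc=mu, scale=sd)
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(v, bins=edges)
    expected = v.size / bins
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=bins - 3))
    return stat, p


def summary_table(
    groups: dict[str, dict[str, list]],
    units: dict[str, str],
    control: str | None = None,
) -> pd.DataFrame:
    """Long-format results table: condition, metric, n, mean, sem, p_vs_control."""
    rows = []
    for condition, metrics in groups.items():
        for metric, values in metrics.items():
            s = summarize(values, condition, units.get(metric, ""))
            p = np.nan
            if control is not None and condition != control and metric in groups[control]:
                ctrl = groups[control][metric]
                if len(ctrl) >= 2 and len(values) >= 2:
                    _, p = compare_groups(values, ctrl)
            rows.append(
                {
                    "condition": condition,
                    "metric": metric,
                    "n": s.n,
                    "mean": s.mean,
                    "sem": s.sem,
                    "unit": s.unit,
                    "p_vs_control": p,
                }
            )
    return pd.DataFrame(rows)
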