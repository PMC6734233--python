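"""Baseline clinical comparisons between episodic and chronic migraine.

Categorical traits (sex, aura, allodynia, anxiety, depression) are compared
with the Pearson chi-square test without continuity correction, switching to
Fisher's exact test when the smallest expected cell count is low; continuous
variables use the Mann-Whitney U test.  These choices reproduce the
conventions of baseline-characteristics tables in clinical studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "compare_baseline_table",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float | None
    pvalue: float
    note: str = ""


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    return t.astype(float)


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square requires all margins > 0")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult("chi-square", float(res[0]), float(res[1]))


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test, two-sided by the 'probabilities <= observed'
    rule (sum of hypergeometric probabilities no larger than the observed
    table's)."""
    t = _as_table(table)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher-exact", None, float(p))


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U: exact enumeration for small untied samples
    (both n <= 8), tie-corrected normal approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:
        # fully tied data carry no ordering information
        return TestResult("mann-whitney", float(x.size * y.size / 2), 1.0,
                          note="degenerate: all values tied")
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      note=method)


def _binary_counts(values: pd.Series, groups: pd.Series, order) -> np.ndarray:
    # rows = groups in given order, columns = (present, absent)
    tab = np.zeros((2, 2))
    for i, g in enumerate(order):
        v = values[groups == g]
        tab[i, 0] = (v == 1).sum()
        tab[i, 1] = (v == 0).sum()
    return tab


def compare_baseline_table(
    phenotype: pd.DataFrame,
    group_col: str = "group",
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    fisher_min_expected: float = 2.5,
) -> pd.DataFrame:
    """Baseline-characteristics comparison of the two groups.

    Binary traits: chi-square without continuity correction unless the
    smallest expected cell count falls below ``fisher_min_expected``, in
    which case Fisher's exact test is used.  Continuous variables:
    Mann-Whitney U.  Constant binary columns get p = 1 by convention and are
    flagged.  Emits one row per variable with per-group summaries
    (mean +/- SD or n (%)) and the p-value.
    """
    groups = phenotype[group_col].astype(str)
    order = sorted(groups.unique())
    if set(order) == {"EM", "CM"}:
        order = ["EM", "CM"]
    if len(order) != 2:
        raise ValueError(f"need exactly two groups, got {order}")

    if continuous is None and binary is None:
        continuous, binary = [], []
        for col in phenotype.columns:
            if col in (group_col, "subject_id"):
                continue
            vals = phenotype[col]
            if not np.issubdtype(vals.dtype, np.number):
                raise ValueError(f"unknown column type for {col!r}")
            if set(vals.unique()) <= {0, 1}:
                binary.append(col)
            else:
                continuous.append(col)
    continuous = continuous or []
    binary = binary or []

    rows = []
    for col in continuous:
        a = phenotype.loc[groups == order[0], col].to_numpy(float)
        b = phenotype.loc[groups == order[1], col].to_numpy(float)
        res = mann_whitney_u(a, b)
        rows.append(
            {
                "variable": col,
                order[0]: f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                order[1]: f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                "test": res.name,
                "p": res.pvalue,
                "note": res.note,
            }
        )
    for col in binary:
        vals = phenotype[col]
        tab = _binary_counts(vals, groups, order)
        summaries = {
            g: f"{int(tab[i, 0])} ({100 * tab[i, 0] / tab[i].sum():.1f}%)"
            for i, g in enumerate(order)
        }
        if len(vals.unique()) < 2:
            rows.append(
                {"variable": col, **summaries, "test": "none",
                 "p": 1.0, "note": "constant column"}
            )
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        if expected.min() < fisher_min_expected:
            res = fisher_exact_2x2(tab)
        else:
            res = chi_square_2x2(tab)
        rows.append(
            {"variable": col, **summaries, "test": res.name,
             "p": res.pvalue, "note": res.note}
        )
    return pd.DataFrame(rows)
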