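"""Group inference on degree centrality and clinical correlates.

The primary test is a label-permutation test on the difference of group
means of per-node degree centrality, with Benjamini-Hochberg FDR correction
across nodes.  Covariate-adjusted group effects are estimated by ordinary
linear models over nested covariate sets, clinical associations by Pearson
correlation, and effect modification by a group x moderator interaction
term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "permutation_group_test",
    "bh_fdr",
    "adjusted_group_effect",
    "correlate_clinical",
    "interaction_effect",
]


@dataclass
class PermutationResult:
    """Observed statistics, permutation null, and (FDR-adjusted) p-values."""

    observed: np.ndarray  # (K,) mean(group B) - mean(group A)
    null: np.ndarray  # (B, K)
    pvalues: np.ndarray  # (K,) two-sided
    pvalues_fdr: np.ndarray
    rejected: np.ndarray  # boolean, adjusted p <= q
    groups: tuple[str, str]  # (A, B); statistic is mean(B) - mean(A)
    n_permutations: int
    exhaustive: bool = False
    node_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.node_names or [f"node{k}" for k in range(len(self.observed))]
        return pd.DataFrame(
            {
                "observed": self.observed,
                "p": self.pvalues,
                "p_fdr": self.pvalues_fdr,
                "rejected": self.rejected,
            },
            index=idx,
        )


def _group_labels(groups) -> tuple[np.ndarray, tuple[str, str]]:
    g = np.asarray(groups)
    uniq = sorted(map(str, np.unique(g).tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    # convention: statistic = mean(CM) - mean(EM) when those labels are used,
    # otherwise mean(later label) - mean(earlier label)
    if set(uniq) == {"EM", "CM"}:
        a, b = "EM", "CM"
    else:
        a, b = uniq
    mask_b = g.astype(str) == b
    if mask_b.sum() == 0 or (~mask_b).sum() == 0:
        raise ValueError("one of the groups is empty")
    return mask_b, (a, b)


def permutation_group_test(
    dc: np.ndarray | pd.DataFrame,
    groups,
    n_permutations: int = 5000,
    alpha: float = 0.05,
    q: float = 0.05,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Two-sided label-permutation test of group mean differences per node.

    Group labels are randomly reassigned (preserving group sizes) and the
    difference of group means recomputed to build a per-node null.  The
    two-sided p-value is ``(1 + #{|T_b| >= |T_obs|}) / (B + 1)``; with
    ``exhaustive=True`` every distinct assignment is enumerated and the exact
    proportion is returned instead.  P-values are then FDR-adjusted across
    nodes (Benjamini-Hochberg, reject at ``q``).
    """
    X = dc.to_numpy() if isinstance(dc, pd.DataFrame) else np.asarray(dc, float)
    if X.ndim == 1:
        X = X[:, None]
    node_names = list(dc.columns) if isinstance(dc, pd.DataFrame) else None
    mask_b, names = _group_labels(groups)
    n, K = X.shape
    if mask_b.shape[0] != n:
        raise ValueError("group labels do not match the number of subjects")
    nb = int(mask_b.sum())
    na = n - nb
    obs = X[mask_b].mean(axis=0) - X[~mask_b].mean(axis=0)

    if exhaustive:
        combos = itertools.combinations(range(n), nb)
        null = np.empty((math.comb(n, nb), K))
        for i, idx in enumerate(combos):
            m = np.zeros(n, bool)
            m[list(idx)] = True
            null[i] = X[m].mean(axis=0) - X[~m].mean(axis=0)
        p = (np.abs(null) >= np.abs(obs) - 1e-12).mean(axis=0)
        B = null.shape[0]
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        B = int(n_permutations)
        # row-wise random subsets of size nb via argpartition of random keys
        keys = rng.random((B, n))
        sel = np.argpartition(keys, nb - 1, axis=1)[:, :nb]
        M = np.zeros((B, n))
        np.put_along_axis(M, sel, 1.0, axis=1)
        null = (M @ X) / nb - ((1.0 - M) @ X) / na
        p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)) / (
            B + 1.0
        )

    p_adj, reject = bh_fdr(p, q=q)
    return PermutationResult(
        observed=obs,
        null=null,
        pvalues=p,
        pvalues_fdr=p_adj,
        rejected=reject,
        groups=names,
        n_permutations=B,
        exhaustive=exhaustive,
        node_names=node_names,
    )


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejections at ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _design(covariates: pd.DataFrame, cols: list[str], group: np.ndarray):
    X = np.column_stack([group] + [covariates[c].to_numpy(float) for c in cols])
    X = sm.add_constant(X, has_constant="add")
    names = ["const", "group"] + cols
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        base = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(names[j])
            else:
                base = cand
        raise ValueError(f"collinear design; offending columns: {bad}")
    return X, names


def adjusted_group_effect(
    dc: np.ndarray | pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_sets: list[list[str]],
    group_col: str = "group",
    q: float = 0.05,
) -> pd.DataFrame:
    """Group-effect p-values from linear models over nested covariate sets.

    For every covariate set, each node's degree centrality is regressed on
    the group indicator plus the covariates; the two-sided p-value of the
    group coefficient is recorded and FDR-adjusted across the node family.
    Returns a long-format frame with columns (covariate_set, node, p, p_fdr).
    """
    X = dc.to_numpy() if isinstance(dc, pd.DataFrame) else np.asarray(dc, float)
    if X.ndim == 1:
        X = X[:, None]
    nodes = (
        list(dc.columns)
        if isinstance(dc, pd.DataFrame)
        else [f"node{k}" for k in range(X.shape[1])]
    )
    mask_b, _ = _group_labels(covariates[group_col])
    group = mask_b.astype(float)
    if group.std() == 0:
        raise ValueError("group indicator is constant; no contrast")
    rows = []
    for cols in covariate_sets:
        design, _ = _design(covariates, list(cols), group)
        pvals = []
        for k in range(X.shape[1]):
            fit = sm.OLS(X[:, k], design).fit()
            pvals.append(float(fit.pvalues[1]))
        p_adj, _ = bh_fdr(pvals, q=q)
        label = " + ".join(cols) if cols else "(unadjusted)"
        for node, p_raw, p_a in zip(nodes, pvals, p_adj):
            rows.append(
                dict(covariate_set=label, node=node, p=p_raw, p_fdr=p_a)
            )
    return pd.DataFrame(rows)


def correlate_clinical(dc: np.ndarray, clinical: np.ndarray):
    """Pearson correlation with two-sided p from the t distribution.

    Returns ``(r, p)``; both inputs must vary and contain >= 3 finite
    observations.
    """
    x = np.asarray(dc, float)
    y = np.asarray(clinical, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def interaction_effect(
    dc: np.ndarray, group, moderator: np.ndarray
) -> dict:
    """P-value of the group x moderator product term in a linear model.

    Fits ``DC ~ group + moderator + group * moderator``; the moderator must
    be binary with every cell of the 2 x 2 group-by-moderator layout
    occupied.
    """
    y = np.asarray(dc, float)
    mask_b, _ = _group_labels(group)
    g = mask_b.astype(float)
    m = np.asarray(moderator, float)
    if set(np.unique(m)) - {0.0, 1.0}:
        raise ValueError("moderator must be binary {0, 1}")
    if len(np.unique(m)) < 2:
        raise ValueError("moderator is constant")
    for gv in (0, 1):
        for mv in (0, 1):
            if not np.any((g == gv) & (m == mv)):
                raise ValueError(
                    f"empty cell in the 2x2 layout: group={gv}, moderator={mv}"
                )
    X = sm.add_constant(np.column_stack([g, m, g * m]))
    fit = sm.OLS(y, X).fit()
    return {
        "p_interaction": float(fit.pvalues[3]),
        "coef_interaction": float(fit.params[3]),
    }
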