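"""Differential-expression calling on two-group count matrices.

The filter contract is |logFC| > 2 and BH-FDR < 0.05 (strict inequalities),
split by the sign of logFC into up- and down-regulated lists. The per-gene
test is a Welch two-sample t-test on log2-CPM values (pseudocount 0.5):
a deliberately simple, documented stand-in for a full negative-binomial
framework — the pipeline's contribution is the filter-and-overlap chain,
not dispersion estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cpm_normalize", "de_test", "bh_adjust", "call_degs", "deg_table"]

UP = "up"
DOWN = "down"
NONE = "none"


def cpm_normalize(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(CPM + pseudocount) normalization of a genes x samples count matrix.

    CPM = count / library_size * 1e6, with the library size the raw column
    total. Adding the pseudocount after the CPM transform makes the result
    exactly invariant to rescaling all counts of one sample.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = counts / lib * 1e6
    return np.log2(cpm + pseudocount)


def _split_groups(norm: pd.DataFrame, groups: pd.Series):
    groups = groups.reindex(norm.columns)
    if groups.isna().any():
        missing = list(norm.columns[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    labels = set(groups)
    if labels != {"treated", "untreated"}:
        raise ValueError(f"group labels must be 'treated'/'untreated', got {sorted(labels)}")
    t = norm.loc[:, (groups == "treated").to_numpy()]
    u = norm.loc[:, (groups == "untreated").to_numpy()]
    if t.shape[1] < 2 or u.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group for the Welch test")
    return t, u


def de_test(norm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene logFC and Welch-test p-value on a normalized matrix.

    logFC = mean(treated) - mean(untreated) on the log2-CPM scale. Genes
    with zero variance in both groups get p = 1 when the means are equal
    (no evidence by convention) and p = 0 when they differ.

    Returns a DataFrame indexed by gene with columns ``logFC`` and ``p``.
    """
    t, u = _split_groups(norm, groups)
    logfc = t.mean(axis=1) - u.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(t, u, axis=1, equal_var=False)
    p = np.asarray(p)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p = p.copy()
        p[degenerate & (logfc.to_numpy() == 0)] = 1.0
        p[degenerate & (logfc.to_numpy() != 0)] = 0.0
    return pd.DataFrame({"logFC": logfc, "p": p}, index=norm.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} min(1, m * p_(j) / j) on the sorted scale.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def call_degs(res: pd.DataFrame, lfc_cut: float = 2.0, fdr_cut: float = 0.05):
    """Call up/down gene lists from a (logFC, fdr) table.

    up: logFC > lfc_cut and fdr < fdr_cut; down: logFC < -lfc_cut and
    fdr < fdr_cut (both strict). Returns (up, down) as sorted lists.
    """
    if "fdr" not in res.columns:
        raise ValueError("result table must carry an 'fdr' column (run bh_adjust first)")
    up = res.index[(res["logFC"] > lfc_cut) & (res["fdr"] < fdr_cut)]
    down = res.index[(res["logFC"] < -lfc_cut) & (res["fdr"] < fdr_cut)]
    return sorted(up), sorted(down)


def deg_table(
    counts: pd.DataFrame,
    groups: pd.Series,
    lfc_cut: float = 2.0,
    fdr_cut: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full DE chain: normalize, test, adjust, call directions.

    Returns a per-gene table with columns ``logFC, p, fdr, direction``
    (direction in {up, down, none}).
    """
    norm = cpm_normalize(counts, pseudocount)
    res = de_test(norm, groups)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    up, down = call_degs(res, lfc_cut, fdr_cut)
    res["direction"] = NONE
    res.loc[up, "direction"] = UP
    res.loc[down, "direction"] = DOWN
    return res
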