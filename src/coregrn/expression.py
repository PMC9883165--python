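"""Expression normalization and differential-expression classification.

Counts tables are genes x samples.  Differential expression uses a Welch
t-test on log2(CPM + 0.5) with Benjamini-Hochberg correction — a simple,
transparent stand-in for the empirical-Bayes linear-model fits used on real
RNA-seq — and classifies genes with the volcano-plot convention:
up = log2FC > 1 and adjusted p < 0.05, down = log2FC < -1 and adjusted
p < 0.05, otherwise unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cpm", "differential_expression"]

LOG_PSEUDOCOUNT = 0.5


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample column; every column sums to 1e6."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    return counts * 1e6 / totals


def differential_expression(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene contrast of condition a over condition b.

    Returns a DataFrame with mean CPM per condition, log2fc (on mean CPM
    with a 0.5 pseudocount), Welch-t p, BH-adjusted p and the volcano
    class.  Requires >= 2 replicates per condition.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition for a variance estimate")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count tables must share the same gene index")
    cpm_a = cpm(counts_a)
    cpm_b = cpm(counts_b)
    mean_a = cpm_a.mean(axis=1)
    mean_b = cpm_b.mean(axis=1)
    log2fc = np.log2((mean_a + LOG_PSEUDOCOUNT) / (mean_b + LOG_PSEUDOCOUNT))

    la = np.log2(cpm_a.to_numpy() + LOG_PSEUDOCOUNT)
    lb = np.log2(cpm_b.to_numpy() + LOG_PSEUDOCOUNT)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    p_adj = stats.false_discovery_control(p, method="bh")

    cls = np.where(
        (log2fc > lfc_threshold) & (p_adj < alpha), "up",
        np.where((log2fc < -lfc_threshold) & (p_adj < alpha), "down", "unchanged"),
    )
    return pd.DataFrame({
        "gene_id": counts_a.index,
        "mean_cpm_a": mean_a.to_numpy(),
        "mean_cpm_b": mean_b.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "p": p,
        "p_adj": p_adj,
        "de_class": cls,
    }).reset_index(drop=True)
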