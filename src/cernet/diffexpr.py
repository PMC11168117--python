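"""Differential expression: CPM normalization, per-feature testing, and the
fold-change + FDR significance gate.

The gate declares a feature differentially expressed when its fold change
between conditions is at least 2 (|log2FC| >= 1, pseudocount 1) and its
Benjamini-Hochberg adjusted p-value is below 0.05.  The per-feature test is
a two-sided Welch t-test on log2(CPM + 1) — a deliberately transparent
engine that is easy to swap for a count-model alternative; the gate and the
downstream network stages only consume (log2fc, fdr, status).

A small RT-qPCR utility implements the 2^-ddCt relative-quantification
formula used to validate sequencing calls against a reference gene.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

__all__ = [
    "cpm_normalize",
    "log2_fold_change",
    "de_test",
    "bh_fdr",
    "call_de",
    "log_expression",
    "ddct_fold_change",
    "write_de_table",
]

FC_THRESHOLD_LOG2 = 1.0   # fold change >= 2, inclusive
FDR_THRESHOLD = 0.05      # strict <
PSEUDOCOUNT = 1.0


def cpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: each column rescaled to sum to 10^6."""
    libsize = matrix.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero library size")
    return matrix.counts / libsize * 1e6


def log2_fold_change(
    mean_cpm_a: float, mean_cpm_b: float, pseudocount: float = PSEUDOCOUNT
) -> float:
    """log2((B + c) / (A + c)); positive = higher in condition B."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((mean_cpm_b + pseudocount) / (mean_cpm_a + pseudocount)))


def de_test(matrix: CountMatrix, group_a: str, group_b: str) -> pd.Series:
    """Two-sided Welch t-test on log2(CPM+1), one p-value per feature.

    Degenerate features (zero variance in both groups) get p = 1 when the
    group means coincide and p = 0 when they differ deterministically.
    """
    samples_a = matrix.samples_in(group_a)
    samples_b = matrix.samples_in(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates in each condition")
    log_cpm = np.log2(cpm_normalize(matrix) + 1.0)
    xa = log_cpm[samples_a].values
    xb = log_cpm[samples_b].values
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    flat = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
    equal_means = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
    pvals = np.where(flat, np.where(equal_means, 1.0, 0.0), pvals)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.Series(pvals, index=matrix.counts.index, name="pvalue")


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    matrix: CountMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    fc_threshold_log2: float = FC_THRESHOLD_LOG2,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Full DE call for one count matrix.

    Returns a DataFrame indexed by feature id with columns
    ``rna_class, mean_cpm_A, mean_cpm_B, log2fc, pvalue, fdr, status``
    where status is ``up`` (log2fc >= threshold and fdr < cutoff),
    ``down`` (log2fc <= -threshold and fdr < cutoff) or ``ns``.
    Conditions default to the two labels in sorted order (A, B); log2fc is
    B versus A.
    """
    conditions = sorted(matrix.conditions)
    if group_a is None or group_b is None:
        group_a, group_b = conditions
    cpm = cpm_normalize(matrix)
    mean_a = cpm[matrix.samples_in(group_a)].mean(axis=1)
    mean_b = cpm[matrix.samples_in(group_b)].mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    pvalues = de_test(matrix, group_a, group_b)
    fdr = bh_fdr(pvalues.values)
    status = np.where(
        (fdr < fdr_threshold) & (log2fc >= fc_threshold_log2),
        "up",
        np.where(
            (fdr < fdr_threshold) & (log2fc <= -fc_threshold_log2), "down", "ns"
        ),
    )
    return pd.DataFrame(
        {
            "rna_class": matrix.rna_class,
            "mean_cpm_A": mean_a,
            "mean_cpm_B": mean_b,
            "log2fc": log2fc,
            "pvalue": pvalues,
            "fdr": fdr,
            "status": status,
        },
        index=matrix.counts.index,
    )


def log_expression(matrix: CountMatrix) -> pd.DataFrame:
    """log2(CPM + 1) expression used for all correlation filtering."""
    return np.log2(cpm_normalize(matrix) + 1.0)


def ddct_fold_change(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each of sample and control;
    ddCt = dCt(sample) - dCt(control); returns 2 ** -ddCt.
    """
    ddct = (ct_target_sample - ct_reference_sample) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0 ** -ddct)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="feature_id")
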