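"""Competing-endogenous-RNA triplet inference.

A ceRNA triplet (ce, miRNA, mRNA) — ce being a lncRNA or circRNA — is
accepted when three criteria hold simultaneously:

1. the miRNA has a predicted seed site on both the ce and the mRNA, and each
   miRNA-target pair is negatively co-expressed: Spearman rank correlation
   (SCC) strictly below -0.7;
2. the ce and the mRNA are positively co-expressed: Pearson correlation
   (PCC) strictly above 0.9;
3. the two transcripts share more regulator miRNAs than chance would give:
   a hypergeometric upper-tail test on the overlap of their miRNA sets with
   p strictly below 0.05.

For a gene pair (A, B) with regulator miRNA sets C and D, the sponge test
evaluates P(X >= x) where x = |C ∩ D|, M = |C|, N = |D| and U is the miRNA
universe of the analysis (by default the number of differential miRNAs):

    p = sum_{k=x}^{min(M,N)} C(M,k) C(U-M, N-k) / C(U,N)

computed by log-factorial accumulation so large universes cannot overflow.
All correlations are computed on log2(CPM+1) across the pooled samples of
both conditions.  Sponge p-values are used raw (no multiplicity
correction) to match the published criterion; an optional BH switch exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffexpr import bh_fdr
from .target_prediction import TargetMap

__all__ = [
    "SCC_THRESHOLD",
    "PCC_THRESHOLD",
    "SPONGE_P_THRESHOLD",
    "CorrEdge",
    "SpongeTest",
    "CeRNATriplet",
    "spearman_rho",
    "pearson_r",
    "sponge_pvalue",
    "candidate_pairs",
    "assemble_triplets",
    "write_triplet_table",
]

SCC_THRESHOLD = -0.7   # miRNA-target edges kept when rho < -0.7 (strict)
PCC_THRESHOLD = 0.9    # ce-mRNA pairs kept when r > 0.9 (strict)
SPONGE_P_THRESHOLD = 0.05  # strict <


@dataclass(frozen=True)
class CorrEdge:
    node_a: str
    node_b: str
    method: str  # "spearman" | "pearson"
    rho: float

    @property
    def passes(self) -> bool:
        if math.isnan(self.rho):
            return False
        if self.method == "spearman":
            return self.rho < SCC_THRESHOLD
        if self.method == "pearson":
            return self.rho > PCC_THRESHOLD
        raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class SpongeTest:
    """Shared-sponge hypergeometric record for one (ceRNA, mRNA) pair."""

    gene_a: str
    gene_b: str
    x: int  # shared regulator miRNAs
    M: int  # |C|, miRNAs regulating gene_a
    N: int  # |D|, miRNAs regulating gene_b
    U: int  # miRNA universe size
    pvalue: float


@dataclass(frozen=True)
class CeRNATriplet:
    ce_id: str
    ce_class: str  # "lncRNA" | "circRNA"
    mirna_id: str
    mrna_id: str
    scc_ce_mirna: float
    scc_mrna_mirna: float
    pcc_ce_mrna: float
    sponge: SpongeTest


def _check_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def spearman_rho(x_values, y_values) -> float:
    """Spearman rank correlation; ties get average fractional ranks.

    Zero variance in either vector makes the coefficient undefined and
    returns NaN (which never passes a threshold).
    """
    x, y = _check_vectors(x_values, y_values)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def pearson_r(x_values, y_values) -> float:
    """Pearson linear correlation; NaN on zero variance."""
    x, y = _check_vectors(x_values, y_values)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def sponge_pvalue(x: int, M: int, N: int, U: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts the overlap when N draws are taken without replacement from a
    universe of U miRNAs containing M marked ones.  Accumulated in log
    space via log-gamma; exact to floating precision for any admissible
    arguments.
    """
    for name, v in (("x", x), ("M", M), ("N", N), ("U", U)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    x, M, N, U = int(x), int(M), int(N), int(U)
    if M > U or N > U:
        raise ValueError("set sizes M, N cannot exceed the universe U")
    if x > min(M, N):
        raise ValueError("overlap x cannot exceed min(M, N)")

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    lo = max(x, M + N - U)
    hi = min(M, N)
    if lo > hi:
        return 0.0
    denom = log_comb(U, N)
    total = 0.0
    for k in range(lo, hi + 1):
        total += math.exp(log_comb(M, k) + log_comb(U - M, N - k) - denom)
    return min(total, 1.0)


def candidate_pairs(
    target_map: TargetMap,
    de_records: pd.DataFrame,
    expression: pd.DataFrame,
    scc_threshold: float = SCC_THRESHOLD,
) -> list[CorrEdge]:
    """Negatively co-expressed (miRNA, target) edges among DE features.

    For every predicted pair whose two members are both differentially
    expressed, the Spearman correlation is computed across all samples;
    only edges with rho strictly below ``scc_threshold`` are returned.
    """
    de_ids = set(de_records.index[de_records["status"] != "ns"])
    edges = []
    for mirna_id, targets in sorted(target_map.targets_of.items()):
        if mirna_id not in de_ids:
            continue
        if mirna_id not in expression.index:
            raise ValueError(f"no expression for miRNA {mirna_id!r}")
        x = expression.loc[mirna_id].values
        for target_id in sorted(targets):
            if target_id not in de_ids:
                continue
            if target_id not in expression.index:
                raise ValueError(f"no expression for target {target_id!r}")
            rho = spearman_rho(x, expression.loc[target_id].values)
            if not math.isnan(rho) and rho < scc_threshold:
                edges.append(CorrEdge(mirna_id, target_id, "spearman", rho))
    return edges


def assemble_triplets(
    mi_target_edges: Sequence[CorrEdge],
    expression: pd.DataFrame,
    de_records: pd.DataFrame,
    universe_u: int | None = None,
    adjust_sponge: bool = False,
    pcc_threshold: float = PCC_THRESHOLD,
    sponge_p_threshold: float = SPONGE_P_THRESHOLD,
) -> list[CeRNATriplet]:
    """Compose accepted miRNA-target edges into ceRNA triplets.

    Every (ce, mRNA) pair sharing at least one passing miRNA is tested for
    positive co-expression (PCC > 0.9) and sponge significance (p < 0.05);
    one triplet is emitted per shared miRNA of each accepted pair, in
    (ce, miRNA, mRNA) lexicographic order.

    ``universe_u`` defaults to the number of differential miRNAs in
    ``de_records`` — the miRNA universe of the analysis.  ``adjust_sponge``
    applies BH correction across the tested pairs before thresholding
    (off by default, matching the raw-p criterion).
    """
    classes = de_records["rna_class"]
    if universe_u is None:
        universe_u = int(
            ((classes == "miRNA") & (de_records["status"] != "ns")).sum()
        )
    mirnas_of: dict[str, set[str]] = {}
    rho_of: dict[tuple[str, str], float] = {}
    for edge in mi_target_edges:
        mirnas_of.setdefault(edge.node_b, set()).add(edge.node_a)
        rho_of[(edge.node_a, edge.node_b)] = edge.rho
    if mirnas_of:
        max_set = max(len(s) for s in mirnas_of.values())
        if universe_u < max_set:
            raise ValueError(
                f"universe U={universe_u} smaller than a per-gene miRNA set "
                f"({max_set})"
            )

    ces = sorted(
        t for t in mirnas_of
        if t in classes.index and classes[t] in ("lncRNA", "circRNA")
    )
    mrnas = sorted(
        t for t in mirnas_of if t in classes.index and classes[t] == "mRNA"
    )

    candidates = []  # (ce, mrna, shared, sponge fields, pcc)
    for ce in ces:
        for mrna in mrnas:
            shared = mirnas_of[ce] & mirnas_of[mrna]
            if not shared:
                continue
            pcc = pearson_r(
                expression.loc[ce].values, expression.loc[mrna].values
            )
            if not (not math.isnan(pcc) and pcc > pcc_threshold):
                continue
            test = SpongeTest(
                ce, mrna, len(shared), len(mirnas_of[ce]),
                len(mirnas_of[mrna]), universe_u,
                sponge_pvalue(
                    len(shared), len(mirnas_of[ce]), len(mirnas_of[mrna]),
                    universe_u,
                ),
            )
            candidates.append((ce, mrna, sorted(shared), test, pcc))

    if adjust_sponge and candidates:
        adjusted = bh_fdr([c[3].pvalue for c in candidates])
    else:
        adjusted = [c[3].pvalue for c in candidates]

    triplets = []
    for (ce, mrna, shared, test, pcc), p_eff in zip(candidates, adjusted):
        if not p_eff < sponge_p_threshold:
            continue
        for mirna in shared:
            triplets.append(
                CeRNATriplet(
                    ce_id=ce,
                    ce_class=str(classes[ce]),
                    mirna_id=mirna,
                    mrna_id=mrna,
                    scc_ce_mirna=rho_of[(mirna, ce)],
                    scc_mrna_mirna=rho_of[(mirna, mrna)],
                    pcc_ce_mrna=pcc,
                    sponge=test,
                )
            )
    triplets.sort(key=lambda t: (t.ce_id, t.mirna_id, t.mrna_id))
    return triplets


def write_triplet_table(triplets: Sequence[CeRNATriplet], path: str | Path) -> None:
    cols = ["ce", "ce_class", "mirna", "mrna", "scc_ce", "scc_mrna", "pcc",
            "x", "M", "N", "U", "p"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in triplets:
            fh.write(
                "\t".join(
                    [
                        t.ce_id, t.ce_class, t.mirna_id, t.mrna_id,
                        f"{t.scc_ce_mirna:.6f}", f"{t.scc_mrna_mirna:.6f}",
                        f"{t.pcc_ce_mrna:.6f}", str(t.sponge.x),
                        str(t.sponge.M), str(t.sponge.N), str(t.sponge.U),
                        f"{t.sponge.pvalue:.6g}",
                    ]
                )
                + "\n"
            )
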