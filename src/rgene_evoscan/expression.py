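"""Differential-expression screening of resistance genes after pathogen
challenge.

The screen keeps genes with |log2 fold change| >= 2 AND
Benjamini–Hochberg FDR <= 0.05 (both inclusive). The per-gene test is an
exact conditional binomial on library-size-normalized summed counts — a
transparent stand-in for a negative-binomial package that preserves the
thresholded contract of the screen. Heatmap matrices order the retained
genes by average-linkage hierarchical clustering of log-scaled profiles,
and cross-pathogen overlaps intersect the up-/down-regulated sets across
experiments.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

DEFAULT_LFC_THRESHOLD = 2.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclasses.dataclass
class DEGRecord:
    gene_id: str
    contrast: str
    log_fc: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down"


def log_fold_change(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_b + pseudocount) / (mean_a + pseudocount))."""
    if not len(group_a) or not len(group_b):
        raise ValueError("empty sample group")
    mean_a = matrix[list(group_a)].mean(axis=1)
    mean_b = matrix[list(group_b)].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def simple_de_test(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """Exact conditional binomial test per gene between two groups.

    Counts are summed within groups; under the null a gene's group-b share
    of its total follows Binomial(total, Nb/(Na+Nb)) where Na, Nb are the
    group library sizes. Two-sided p-values.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("empty sample group")
    a = counts[list(group_a)].sum(axis=1)
    b = counts[list(group_b)].sum(axis=1)
    lib_a = float(counts[list(group_a)].to_numpy().sum())
    lib_b = float(counts[list(group_b)].to_numpy().sum())
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("zero library size")
    p_null = lib_b / (lib_a + lib_b)
    pvals = np.ones(len(counts))
    for i, (xa, xb) in enumerate(zip(a.to_numpy(), b.to_numpy())):
        total = int(round(xa + xb))
        if total == 0:
            continue
        pvals[i] = stats.binomtest(int(round(xb)), total, p_null).pvalue
    return pd.Series(pvals, index=counts.index, name="p_value")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running_min = min(running_min, p[idx] * m / (rank + 1))
        adjusted[idx] = running_min
    return adjusted


def screen_degs(
    log_fc: pd.Series,
    fdr: pd.Series,
    contrast: str = "",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[DEGRecord]:
    """Keep genes with |logFC| >= lfc_threshold AND FDR <= fdr_threshold
    (both thresholds inclusive); direction by the sign of logFC."""
    out = []
    for gene in log_fc.index:
        lfc = float(log_fc[gene])
        q = float(fdr[gene])
        if abs(lfc) >= lfc_threshold and q <= fdr_threshold:
            out.append(
                DEGRecord(
                    gene_id=str(gene),
                    contrast=contrast,
                    log_fc=lfc,
                    p_value=float("nan"),
                    fdr=q,
                    direction="up" if lfc > 0 else "down",
                )
            )
    return out


def de_screen(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, list[DEGRecord]]:
    """Full screen: logFC + binomial test + BH + thresholds.

    Returns (per-gene table, DEG records).
    """
    lfc = log_fold_change(counts, group_a, group_b, pseudocount)
    pvals = simple_de_test(counts, group_a, group_b)
    fdr = pd.Series(bh_adjust(pvals.to_numpy()), index=counts.index, name="fdr")
    table = pd.DataFrame({"log_fc": lfc, "p_value": pvals, "fdr": fdr})
    degs = screen_degs(lfc, fdr, contrast, lfc_threshold, fdr_threshold)
    for rec in degs:
        rec.p_value = float(pvals[rec.gene_id])
    return table, degs


def heatmap_matrix(
    matrix: pd.DataFrame,
    deg_genes: Sequence[str],
    sample_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rows restricted to the DEG set, ordered by average-linkage
    hierarchical clustering on Euclidean distances of log2(x+1) rows;
    deterministic tie-breaking via a stable pre-sort by gene id."""
    genes = sorted(set(deg_genes))
    if not genes:
        warnings.warn("empty DEG set: heatmap matrix is empty")
        return matrix.iloc[0:0]
    sub = matrix.loc[genes]
    if sample_order is not None:
        sub = sub[list(sample_order)]
    if len(genes) > 2:
        scaled = np.log2(sub.to_numpy(dtype=float) + 1.0)
        order = leaves_list(average(pdist(scaled)))
        sub = sub.iloc[order]
    return sub


def cross_pathogen_overlap(
    deg_sets: dict[str, Sequence[DEGRecord]],
) -> dict[str, set[str]]:
    """Genes consistently up- (resp. down-) regulated across experiments."""
    ups = []
    downs = []
    for records in deg_sets.values():
        ups.append({r.gene_id for r in records if r.direction == "up"})
        downs.append({r.gene_id for r in records if r.direction == "down"})
    return {
        "up": set.intersection(*ups) if ups else set(),
        "down": set.intersection(*downs) if downs else set(),
    }


def degs_table(degs: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(d) for d in degs],
        columns=["gene_id", "contrast", "log_fc", "p_value", "fdr", "direction"],
    )
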