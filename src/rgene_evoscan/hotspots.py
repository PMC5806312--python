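"""Chromosomal duplication-hotspot mapping.

Gene positions are binned per chromosome in fixed windows (1 Mb by
default, 0-based half-open, assignment by start coordinate). Within each
chromosome the bins form a one-way layout with species as replicates;
Duncan's multiple range test at alpha groups the bin means, and a bin is
called a (shared) hotspot when its mean exceeds the chromosome's typical
level and no homogeneous letter group joins it with the bin nearest the
grand mean. Because species are the replicates, a flagged bin is by
construction elevated across species — the "shared hotspot" notion.

Telomeric fractions report the share of a chromosome's genes lying in
hotspot bins within a terminal window at either chromosome end.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BIN_SIZE = 1_000_000


from functools import lru_cache


@lru_cache(maxsize=4096)
def _least_significant_range(p: int, df_error: int, alpha: float) -> float:
    """Duncan's significant studentized range at protection level
    1 - (1-alpha)^(p-1) for a stretch of p ranked means."""
    protection = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - protection, p, df_error))


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_genes(
    coordinates: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Per-(chromosome, bin, species) gene counts over a complete bin grid.

    ``coordinates`` needs columns chrom, start, gene_id, species (0-based
    half-open; genes are assigned by start). A gene starting at or beyond
    its chromosome's declared length is an error.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    species = sorted(coordinates["species"].unique()) if len(coordinates) else []
    grids = []
    for chrom, length in sorted(chromosome_lengths.items()):
        n_bins = int(np.ceil(length / bin_size))
        for b in range(n_bins):
            grids.append((chrom, b))
    counts = {g: {sp: 0 for sp in species} for g in grids}
    for _, row in coordinates.iterrows():
        chrom = row["chrom"]
        if chrom not in chromosome_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        start = int(row["start"])
        if start >= chromosome_lengths[chrom]:
            raise ValueError(
                f"gene {row['gene_id']} at {start} beyond {chrom} length "
                f"{chromosome_lengths[chrom]}"
            )
        counts[(chrom, start // bin_size)][row["species"]] += 1
    rows = []
    for (chrom, b), per_sp in counts.items():
        rows.append(
            {
                "chrom": chrom,
                "bin": b,
                "bin_start": b * bin_size,
                "bin_end": (b + 1) * bin_size,
                **per_sp,
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "bin", "bin_start", "bin_end"] + species)
    return df.sort_values(["chrom", "bin"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def duncan_groups(
    means: np.ndarray, mse: float, df_error: int, n_rep: int, alpha: float = 0.05
) -> list[set[int]]:
    """Duncan's multiple range procedure on a set of group means.

    Means are ranked; a stretch of p consecutive ranked means is declared
    homogeneous when its range falls below the least significant range
    ``R_p = q(1 - (1-alpha)^(p-1); p, df) * sqrt(MSE / n_rep)`` (the
    studentized range at Duncan's protection level). Returns the maximal
    homogeneous stretches (letter groups) as sets of original indices.
    """
    k = len(means)
    order = np.argsort(means)[::-1]  # descending
    sorted_means = means[order]
    if df_error < 1 or mse <= 0:
        # no residual variation: every distinct mean is its own group
        groups = []
        for v in sorted(set(means), reverse=True):
            groups.append({i for i in range(k) if means[i] == v})
        return groups

    def lsr(p: int) -> float:
        return _least_significant_range(p, df_error, alpha) * np.sqrt(mse / n_rep)

    homogeneous = np.zeros((k, k), dtype=bool)
    for i in range(k):
        homogeneous[i, i] = True
        for j in range(i + 1, k):
            p = j - i + 1
            span = sorted_means[i] - sorted_means[j]
            homogeneous[i, j] = span <= lsr(p)
    # protection rule: no difference inside a nonsignificant stretch may be
    # declared significant — widest stretches first
    for width in range(k - 1, 0, -1):
        for i in range(0, k - width):
            j = i + width
            if homogeneous[i, j]:
                homogeneous[i : j + 1, i : j + 1] = np.triu(
                    np.ones((width + 1, width + 1), dtype=bool)
                ) | homogeneous[i : j + 1, i : j + 1]
    groups: list[set[int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous[i, j + 1]:
            j += 1
        stretch = {int(order[t]) for t in range(i, j + 1)}
        if not any(stretch <= g for g in groups):
            groups.append(stretch)
    return groups


def detect_hotspots(
    bins: pd.DataFrame,
    species: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Duncan-test hotspot calls per chromosome.

    ``bins`` is a bin_genes() table. For each chromosome the per-species
    counts of each bin are the replicates. A bin is a hotspot when its
    mean exceeds that of the bin nearest the chromosome grand mean and no
    Duncan letter group contains both. With species as replicates, flagged
    bins are elevated jointly across species, i.e. shared.
    """
    if species is None:
        species = [
            c for c in bins.columns
            if c not in ("chrom", "bin", "bin_start", "bin_end")
        ]
    if len(species) < 2:
        raise ValueError("need >= 2 species (replicates)")
    out = []
    for chrom, sub in bins.groupby("chrom"):
        sub = sub.sort_values("bin")
        data = sub[species].to_numpy(dtype=float)  # bins x species
        k, r = data.shape
        if k < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 bins")
        means = data.mean(axis=1)
        grand = data.mean()
        mse = float(data.var(axis=1, ddof=1).mean())
        df_error = k * (r - 1)
        if np.ptp(data) == 0:
            flags = np.zeros(k, dtype=bool)
        else:
            groups = duncan_groups(means, mse, df_error, r, alpha)
            anchor = int(np.argmin(np.abs(means - grand)))
            flags = np.zeros(k, dtype=bool)
            for b in range(k):
                if means[b] <= means[anchor]:
                    continue
                together = any(b in g and anchor in g for g in groups)
                flags[b] = not together
        for row_i, (_, row) in enumerate(sub.iterrows()):
            out.append(
                {
                    "chrom": chrom,
                    "bin": int(row["bin"]),
                    "bin_start": int(row["bin_start"]),
                    "bin_end": int(row["bin_end"]),
                    "mean_count": float(means[row_i]),
                    "hotspot": bool(flags[row_i]),
                    **{sp: int(row[sp]) for sp in species},
                }
            )
    return pd.DataFrame(out)


def telomeric_fraction(
    hotspot_table: pd.DataFrame,
    coordinates: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    terminal_window_bins: int = 2,
) -> pd.DataFrame:
    """Per-chromosome percent of genes lying in terminal hotspot bins.

    Terminal = within ``terminal_window_bins`` of either chromosome end.
    """
    rows = []
    for chrom, length in sorted(chromosome_lengths.items()):
        n_bins = int(np.ceil(length / bin_size))
        terminal = set(range(terminal_window_bins)) | set(
            range(max(n_bins - terminal_window_bins, 0), n_bins)
        )
        hot = hotspot_table[
            (hotspot_table["chrom"] == chrom) & hotspot_table["hotspot"]
        ]["bin"]
        hot_terminal = {b for b in hot if b in terminal}
        genes = coordinates[coordinates["chrom"] == chrom]
        total = len(genes)
        in_hot = sum(
            1 for _, g in genes.iterrows() if (int(g["start"]) // bin_size) in hot_terminal
        )
        rows.append(
            {
                "chrom": chrom,
                "n_genes": total,
                "n_in_terminal_hotspots": in_hot,
                "fraction_pct": (100.0 * in_hot / total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
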