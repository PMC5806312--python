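"""Detection of sequence-exchange (gene-conversion) events within families.

A Sawyer-type maximal-fragment statistic: restricted to the family's
polymorphic columns, each sequence pair is scanned for its best-scoring
contiguous run (+1 per match, -penalty per mismatch; the default penalty
equals the number of polymorphic sites, so any mismatch resets the run —
the analogue of a zero mismatch tolerance). Significance comes from
permuting the order of polymorphic columns jointly across the family and
comparing each observed pair score to the null distribution of the
family-wide maximum (a family-wise "global" p-value). Events are pairs
with global p below alpha, classified paralog/ortholog by species.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class ConversionEvent:
    family_id: str
    gene_a: str
    gene_b: str
    start: int  # alignment column (0-based) of the fragment
    end: int  # inclusive
    score: float
    p_value: float
    relation: str = "unknown"


def polymorphic_columns(alignment: dict[str, str]) -> list[int]:
    """Columns holding >= 2 distinct non-gap residues across the family."""
    if not alignment:
        return []
    rows = list(alignment.values())
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("sequences must be aligned (equal length)")
    out = []
    for j in range(length):
        residues = {r[j] for r in rows if r[j] not in "-.Nn"}
        if len(residues) >= 2:
            out.append(j)
    return out


def max_fragment_score(
    seq_a: str,
    seq_b: str,
    columns: Sequence[int],
    mismatch_penalty: float | None = None,
) -> tuple[float, int, int]:
    """Best-scoring contiguous segment over the polymorphic columns.

    Kadane scan; +1 per matching column, -penalty per mismatch (default
    penalty = number of polymorphic columns, so one mismatch resets).
    Ties break leftmost-longest. Returns (score, start_col, end_col) in
    original alignment coordinates; (0, -1, -1) if no positive segment.
    """
    cols = list(columns)
    if not cols:
        raise ValueError("no polymorphic columns")
    if mismatch_penalty is None:
        mismatch_penalty = float(len(cols))
    scores = np.array(
        [1.0 if seq_a[j] == seq_b[j] else -float(mismatch_penalty) for j in cols]
    )
    best = 0.0
    best_range = (-1, -1)
    run = 0.0
    run_start = 0
    for i, s in enumerate(scores):
        if run <= 0:
            run = s
            run_start = i
        else:
            run += s
        if run > 0:
            better = run > best
            tie = run == best and best_range != (-1, -1)
            if tie:
                leftmost = run_start < best_range[0]
                longer_same_start = (
                    run_start == best_range[0]
                    and (i - run_start) > (best_range[1] - best_range[0])
                )
                better = leftmost or longer_same_start
            if better:
                best = run
                best_range = (run_start, i)
    if best_range == (-1, -1):
        return 0.0, -1, -1
    return float(best), cols[best_range[0]], cols[best_range[1]]


def _pair_scores(seqs: list[str], cols: np.ndarray, penalty: float) -> np.ndarray:
    """Max fragment score for every pair, Kadane scan vectorized across
    all pairs at once."""
    n = len(seqs)
    arr = np.array([list(s) for s in seqs])[:, cols]
    iu, ju = np.triu_indices(n, 1)
    vals = np.where(arr[iu] == arr[ju], 1.0, -penalty)  # npairs x ncols
    run = np.zeros(len(iu))
    best = np.zeros(len(iu))
    for j in range(vals.shape[1]):
        np.maximum(run, 0.0, out=run)
        run += vals[:, j]
        np.maximum(best, run, out=best)
    out = np.zeros((n, n))
    out[iu, ju] = best
    return out


def permutation_test(
    alignment: dict[str, str],
    family_id: str = "",
    species_of: dict[str, str] | None = None,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    mismatch_penalty: float | None = None,
    global_null: bool = True,
) -> list[ConversionEvent]:
    """Permutation test for sequence-exchange fragments in one family.

    The null permutes the order of polymorphic columns (jointly across all
    sequences) and recomputes every pair's best fragment; each observed
    pair score is referred to the null distribution of the family-wide
    maximum score (or, with ``global_null=False``, to that pair's own null).
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    names = sorted(alignment)
    cols = polymorphic_columns(alignment)
    if not cols:
        return []
    cols = np.array(cols)
    penalty = float(len(cols)) if mismatch_penalty is None else float(mismatch_penalty)
    seqs = [alignment[n] for n in names]
    observed = _pair_scores(seqs, cols, penalty)
    rng = np.random.default_rng(seed)
    n = len(names)
    exceed = np.zeros((n, n))
    for _ in range(n_permutations):
        perm = rng.permutation(cols)
        null_scores = _pair_scores(seqs, perm, penalty)
        null_ref = null_scores.max() if global_null else null_scores
        exceed += null_ref >= observed
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    events = []
    for i in range(n):
        for j in range(i + 1, n):
            if pvals[i, j] < alpha and observed[i, j] > 0:
                score, start, end = max_fragment_score(
                    alignment[names[i]], alignment[names[j]], cols.tolist(), penalty
                )
                relation = "unknown"
                if species_of is not None:
                    relation = (
                        "paralog"
                        if species_of[names[i]] == species_of[names[j]]
                        else "ortholog"
                    )
                events.append(
                    ConversionEvent(
                        family_id=family_id,
                        gene_a=names[i],
                        gene_b=names[j],
                        start=start,
                        end=end,
                        score=score,
                        p_value=float(pvals[i, j]),
                        relation=relation,
                    )
                )
    return events


def classify_events(events: Sequence[ConversionEvent]) -> dict:
    """Totals and the paralog share among significant events."""
    n_paralog = sum(1 for e in events if e.relation == "paralog")
    n_ortholog = sum(1 for e in events if e.relation == "ortholog")
    total = len(events)
    return {
        "n_events": total,
        "n_paralog": n_paralog,
        "n_ortholog": n_ortholog,
        "paralog_pct": (100.0 * n_paralog / total) if total else float("nan"),
    }


def events_table(events: Sequence[ConversionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(e) for e in events],
        columns=[
            "family_id", "gene_a", "gene_b", "start", "end",
            "score", "p_value", "relation",
        ],
    )
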