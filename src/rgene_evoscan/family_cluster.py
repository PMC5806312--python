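"""Multi-gene family clustering by pairwise identity and coverage.

Genes are clustered separately within the TNL and non-TNL supergroups:
an edge joins two genes when alignment identity and coverage both exceed
60% (strictly), and families are the single-linkage connected components.
Components of size one are tracked as singletons.

Pairwise metrics come from a deterministic global alignment (match +1,
mismatch -1, gap open -5, gap extend -2): identity is the percent of
matching columns over aligned (non-double-gap) columns, coverage the
percent of the shorter sequence spanned by aligned residue pairs.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_ID_THRESHOLD = 60.0
DEFAULT_COV_THRESHOLD = 60.0


@dataclasses.dataclass(frozen=True)
class PairSimilarity:
    gene_a: str
    gene_b: str
    identity: float  # percent
    coverage: float  # percent

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 100.0):
            raise ValueError("identity and coverage must be percentages")


@dataclasses.dataclass
class GeneFamily:
    family_id: str
    members: list[str]
    supergroup: str
    mean_identity: float


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # free end gaps: a contained sequence aligns without terminal penalty
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def pairwise_similarity(
    gene_a: str, seq_a: str, gene_b: str, seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> PairSimilarity:
    """Alignment-column identity and shorter-sequence coverage for a pair.

    Identity is taken over the aligned span — the columns between the
    first and last residue pairing — so internal gaps dilute identity but
    terminal overhangs (e.g. a sequence contained in a longer one) do not.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = _aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    paired_cols = [
        i for i, (ca, cb) in enumerate(zip(a, b)) if ca != "-" and cb != "-"
    ]
    shorter = min(len(seq_a), len(seq_b))
    if not paired_cols:
        return PairSimilarity(gene_a, gene_b, 0.0, 0.0)
    span = range(paired_cols[0], paired_cols[-1] + 1)
    matches = sum(1 for i in span if a[i] == b[i] and a[i] != "-")
    identity = 100.0 * matches / len(span)
    coverage = 100.0 * len(paired_cols) / shorter
    return PairSimilarity(gene_a, gene_b, identity, min(coverage, 100.0))


def all_pairwise_similarities(
    sequences: dict[str, str],
) -> list[PairSimilarity]:
    aligner = _aligner()
    names = sorted(sequences)
    return [
        pairwise_similarity(a, sequences[a], b, sequences[b], aligner)
        for a, b in itertools.combinations(names, 2)
    ]


def cluster_families(
    genes: Sequence[str],
    similarities: Iterable[PairSimilarity],
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage components of the identity/coverage graph.

    Edges require identity > id_threshold AND coverage > cov_threshold,
    both strict. Returns (families sorted by first member, singletons);
    together they partition ``genes``.
    """
    for name, thr in (("id_threshold", id_threshold), ("cov_threshold", cov_threshold)):
        if not 0.0 <= thr <= 100.0:
            raise ValueError(f"{name} must be within [0, 100]")
    genes = sorted(set(genes))
    index = {g: i for i, g in enumerate(genes)}
    rows, cols = [], []
    for sim in similarities:
        if sim.gene_a not in index or sim.gene_b not in index:
            continue
        if sim.identity > id_threshold and sim.coverage > cov_threshold:
            rows.append(index[sim.gene_a])
            cols.append(index[sim.gene_b])
    n = len(genes)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    comps: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        comps.setdefault(int(lab), []).append(g)
    families = sorted(
        (sorted(members) for members in comps.values() if len(members) >= 2),
        key=lambda m: m[0],
    )
    singletons = sorted(
        m[0] for m in comps.values() if len(m) == 1
    )
    return families, singletons


def cluster_by_supergroup(
    sequences: dict[str, str],
    supergroup_of: dict[str, str],
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> tuple[list[GeneFamily], list[str], list[PairSimilarity]]:
    """Cluster TNLs and non-TNLs separately; family ids are prefixed by
    supergroup (``TNL_family0`` ...)."""
    families: list[GeneFamily] = []
    singletons: list[str] = []
    all_sims: list[PairSimilarity] = []
    for sg in ("TNL", "non-TNL"):
        members = {g: s for g, s in sequences.items() if supergroup_of.get(g) == sg}
        if not members:
            continue
        sims = all_pairwise_similarities(members)
        all_sims.extend(sims)
        fams, singles = cluster_families(
            list(members), sims, id_threshold, cov_threshold
        )
        sim_map = {frozenset((s.gene_a, s.gene_b)): s.identity for s in sims}
        prefix = "TNL" if sg == "TNL" else "nonTNL"
        for k, mem in enumerate(fams):
            idents = [
                sim_map[frozenset(p)] for p in itertools.combinations(mem, 2)
            ]
            families.append(
                GeneFamily(
                    family_id=f"{prefix}_family{k}",
                    members=mem,
                    supergroup=sg,
                    mean_identity=float(np.mean(idents)),
                )
            )
        singletons.extend(singles)
    return families, singletons, all_sims


def copy_number_matrix(
    families: list[GeneFamily], species_of: dict[str, str]
) -> pd.DataFrame:
    """Per-family x species copy counts with min-max range columns."""
    species = sorted(set(species_of.values()))
    rows = []
    for fam in families:
        counts = {sp: 0 for sp in species}
        for g in fam.members:
            counts[species_of[g]] += 1
        row = {"family_id": fam.family_id, "supergroup": fam.supergroup, **counts}
        vals = list(counts.values())
        row["min_copies"] = min(vals)
        row["max_copies"] = max(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def family_summary(
    families: list[GeneFamily],
    singletons: list[str],
    species_of: dict[str, str],
) -> pd.DataFrame:
    """Per-species and total multi-gene statistics.

    Proportion of multi-gene = multi / (multi + single) per column; the
    per-supergroup "average identity" is the mean over families of each
    family's mean pairwise identity.
    """
    species = sorted(set(species_of.values()))
    cols = species + ["Total"]

    def counts(genes: Iterable[str]):
        c = {sp: 0 for sp in cols}
        for g in genes:
            c[species_of[g]] += 1
            c["Total"] += 1
        return c

    multi = counts(g for f in families for g in f.members)
    single = counts(singletons)
    rows = {
        "n_multi_gene": multi,
        "n_single_gene": single,
        "proportion_multi_gene_pct": {
            k: (100.0 * multi[k] / (multi[k] + single[k]))
            if (multi[k] + single[k])
            else float("nan")
            for k in cols
        },
    }
    for sg, key in (("TNL", "TNL"), ("non-TNL", "nonTNL")):
        fams = [f for f in families if f.supergroup == sg]
        m = counts(g for f in fams for g in f.members)
        rows[f"n_{key}_multi_gene"] = m
        rows[f"n_{key}_families"] = {k: (len(fams) if k == "Total" else float("nan"))
                                     for k in cols}
        rows[f"mean_identity_{key}_pct"] = {
            k: (float(np.mean([f.mean_identity for f in fams]))
                if (k == "Total" and fams) else float("nan"))
            for k in cols
        }
    return pd.DataFrame(rows).T[cols]


def multi_gene_proportion(n_multi: int, n_total: int) -> float:
    """Percent of genes that belong to multi-gene families."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * n_multi / n_total


def compare_identity_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> dict:
    """Welch two-sample t-test between two identity (or rate) groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    out = {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
    if a.size < 2 or b.size < 2:
        out["t"] = float("nan")
        out["p"] = float("nan")
        out["test"] = "undefined (group with < 2 values)"
        return out
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        out["t"], out["p"] = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["t"], out["p"] = float(t), float(p)
    out["test"] = "Welch t-test"
    return out
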