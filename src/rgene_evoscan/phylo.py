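"""Gene-tree construction and duplication-clade typing.

Trees are built by neighbor joining on Jukes–Cantor distances — a
deterministic, dependency-free route that is sufficient for branch-length
summaries and for typing duplication clades. Externally computed Newick
trees can be loaded instead via :func:`read_newick`.

Leaf names follow the ``species|gene_id`` convention; species can also be
supplied as an explicit mapping.
"""

from __future__ import annotations

import io
import math
from collections import Counter

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


def species_of_leaf(label: str) -> str:
    """Species from a ``species|gene_id`` leaf label."""
    if "|" not in label:
        raise ValueError(f"leaf label {label!r} has no 'species|gene' separator")
    return label.split("|", 1)[0]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jc_distance(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); p >= 3/4 saturates."""
    if p < 0:
        raise ValueError("p-distance must be nonnegative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(alignment: dict[str, str]) -> pd.DataFrame:
    """Pairwise JC distances over a nucleotide alignment.

    Gap/ambiguous positions are deleted pairwise. A pair with p >= 3/4
    (saturated) or no comparable sites gets NaN.
    """
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(alignment[n].upper()) for n in names])
    if len({s.shape[0] for s in arr}) > 1:
        raise ValueError("sequences must be aligned (equal length)")
    valid = np.isin(arr, list("ACGT"))
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nsites = int(both.sum())
            if nsites == 0:
                d[i, j] = d[j, i] = math.nan
                continue
            p = float((arr[i][both] != arr[j][both]).sum()) / nsites
            d[i, j] = d[j, i] = jc_distance(p)
    return pd.DataFrame(d, index=names, columns=names)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distances: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the smallest (row, col) index
    pair in the current label order; negative branch lengths are clamped
    to zero. Returns an unrooted (trifurcating-root) dendropy tree.
    """
    labels = list(distances.index)
    d = distances.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValueError("need a square matrix with >= 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains invalid entries")
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    active = list(range(len(labels)))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first occurrence: row-major
        i, j = sorted(best)
        fi, fj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[fi].edge.length = li
        nodes[fj].edge.length = lj
        parent.add_child(nodes[fi])
        parent.add_child(nodes[fj])
        # distances from the new node
        new_row = 0.5 * (d[fi, :] + d[fj, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        new_index = d.shape[0] - 1
        active = [a for a in active if a not in (fi, fj)] + [new_index]

    fi, fj = active
    root = dendropy.Node()
    half = max(d[fi, fj], 0.0)
    nodes[fi].edge.length = half / 2.0
    nodes[fj].edge.length = half / 2.0
    root.add_child(nodes[fi])
    root.add_child(nodes[fj])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def nj_tree(alignment: dict[str, str]) -> dendropy.Tree:
    """NJ tree from a nucleotide alignment via JC distances."""
    return neighbor_joining(jc_distance_matrix(alignment))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if source.strip().startswith("("):
        return dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
    return dendropy.Tree.get(path=source, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# duplication-clade typing
# ---------------------------------------------------------------------------

def label_duplication_clades(
    tree: dendropy.Tree,
    species_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Type internal nodes as speciation vs duplication nodes and report
    maximal duplication clades.

    An internal node is a duplication node iff the species sets of its two
    child subtrees intersect. A duplication node whose subtree holds one
    species is *species-specific*; with two or more species it is
    *lineage-specific* (duplication in a common ancestor, so each duplicate
    lineage carries orthologs from several genomes). Maximal clades only:
    a duplication node nested inside a reported clade is not reported again.

    Returns a table with one row per internal node: node id, type, whether
    it heads a maximal duplication clade, genes and species in its subtree.
    """
    if not tree.is_rooted:
        tree = midpoint_root(tree)
    species_sets: dict = {}
    gene_counts: dict = {}
    rows = []
    node_ids = {}
    for i, node in enumerate(tree.postorder_node_iter()):
        node_ids[node] = i
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if species_map is not None:
                if label not in species_map:
                    raise KeyError(f"leaf {label!r} has no species label")
                sp = species_map[label]
            else:
                sp = species_of_leaf(label)
            species_sets[node] = {sp}
            gene_counts[node] = 1
        else:
            children = node.child_nodes()
            species_sets[node] = set().union(*(species_sets[c] for c in children))
            gene_counts[node] = sum(gene_counts[c] for c in children)

    def is_duplication(node) -> bool:
        children = node.child_nodes()
        if len(children) < 2:
            return False
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                if species_sets[children[a]] & species_sets[children[b]]:
                    return True
        return False

    inside_dup: set = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        dup = is_duplication(node)
        if dup:
            kind = (
                "species-specific" if len(species_sets[node]) == 1 else "lineage-specific"
            )
        else:
            kind = "speciation"
        maximal = dup and node not in inside_dup
        if dup:
            for desc in node.preorder_iter():
                if desc is not node:
                    inside_dup.add(desc)
        rows.append(
            {
                "node": node_ids[node],
                "type": kind,
                "maximal_clade": maximal,
                "n_genes": gene_counts[node],
                "n_species": len(species_sets[node]),
                "species": ",".join(sorted(species_sets[node])),
            }
        )
    return pd.DataFrame(rows)


def clade_type_summary(labels: pd.DataFrame) -> dict:
    """Counts of maximal duplication clades and genes by clade type."""
    maximal = labels[labels["maximal_clade"]]
    out = Counter()
    genes = Counter()
    for _, row in maximal.iterrows():
        out[row["type"]] += 1
        genes[row["type"]] += row["n_genes"]
    return {
        "n_lineage_specific": out.get("lineage-specific", 0),
        "n_species_specific": out.get("species-specific", 0),
        "genes_lineage_specific": genes.get("lineage-specific", 0),
        "genes_species_specific": genes.get("species-specific", 0),
    }


# ---------------------------------------------------------------------------
# branch-length contrasts
# ---------------------------------------------------------------------------

def branch_lengths_by_group(
    trees: list[dendropy.Tree],
    group_of_gene: dict[str, str],
) -> dict[str, list[float]]:
    """Collect branch lengths per declared gene group.

    A terminal branch belongs to its leaf's group; an internal branch to a
    group iff every leaf below it maps to that single group.
    """
    if not trees:
        raise ValueError("no trees supplied")
    out: dict[str, list[float]] = {}
    for tree in trees:
        leaf_groups: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                leaf_groups[node] = {group_of_gene.get(label)}
            else:
                leaf_groups[node] = set().union(
                    *(leaf_groups[c] for c in node.child_nodes())
                )
            groups = leaf_groups[node]
            if len(groups) == 1 and None not in groups and node.edge.length is not None:
                (g,) = groups
                out.setdefault(g, []).append(float(node.edge.length))
    return out


def branch_length_contrast(
    trees: list[dendropy.Tree],
    group_of_gene: dict[str, str],
) -> pd.DataFrame:
    """Group mean branch lengths with Welch t-tests between every pair."""
    groups = branch_lengths_by_group(trees, group_of_gene)
    names = sorted(groups)
    rows = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            xa, xb = groups[a], groups[b]
            row = {
                "group_a": a,
                "group_b": b,
                "mean_a": float(np.mean(xa)),
                "mean_b": float(np.mean(xb)),
                "n_a": len(xa),
                "n_b": len(xb),
            }
            if len(xa) >= 2 and len(xb) >= 2:
                if (
                    np.ptp(xa) == 0
                    and np.ptp(xb) == 0
                    and np.mean(xa) == np.mean(xb)
                ):
                    row["t"], row["p"] = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(xa, xb, equal_var=False)
                    row["t"] = float(t)
                    row["p"] = float(p)
            else:
                row["t"] = math.nan
                row["p"] = math.nan
            rows.append(row)
    return pd.DataFrame(rows)
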