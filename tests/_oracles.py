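"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (standard
genetic code via Biopython, exhaustive enumeration, quadratic scans)
without importing the implementation's counting tables.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_NTS = "ACGT"


def ng86_brute_force(seq_a: str, seq_b: str):
    """(Ka, Ks) by direct enumeration of site fractions and pathways.

    Returns (ka, ks) with None for saturated/undefined values. Implements
    the classical counting: per-position synonymous fractions with stop
    changes excluded from the possible-change set; differences averaged
    over all minimal pathways avoiding stops (all pathways if none avoid).
    """
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_sites = {"a": 0.0, "b": 0.0}
    sd = 0.0
    nd = 0.0
    n_codons = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if ca in _STOPS or cb in _STOPS or ca not in _AA or cb not in _AA:
            continue
        n_codons += 1
        for key, codon in (("a", ca), ("b", cb)):
            for pos in range(3):
                changes = []
                for nt in _NTS:
                    if nt == codon[pos]:
                        continue
                    alt = codon[:pos] + nt + codon[pos + 1 :]
                    if alt in _STOPS:
                        continue
                    changes.append(_AA[alt] == _AA[codon])
                if changes:
                    s_sites[key] += sum(changes) / len(changes)
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if diff:
            paths = []
            for order in itertools.permutations(diff):
                syn = non = 0
                cur = ca
                ok = True
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if nxt in _STOPS:
                        ok = False
                        break
                    if _AA[nxt] == _AA[cur]:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                if ok:
                    paths.append((syn, non))
            if not paths:
                for order in itertools.permutations(diff):
                    syn = non = 0
                    cur = ca
                    for pos in order:
                        nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                        if nxt not in _STOPS and _AA.get(nxt) == _AA.get(cur):
                            syn += 1
                        else:
                            non += 1
                        cur = nxt
                    paths.append((syn, non))
            sd += sum(p[0] for p in paths) / len(paths)
            nd += sum(p[1] for p in paths) / len(paths)
    if n_codons == 0:
        raise ValueError("no comparable codons")
    s = 0.5 * (s_sites["a"] + s_sites["b"])
    n = 3 * n_codons - s

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(sd / s) if s > 0 else jc(0.0)
    ka = jc(nd / n) if n > 0 else jc(0.0)
    return ka, ks, s, n


def max_segment_quadratic(values):
    """Best (score, start, end) over all contiguous segments; leftmost-
    longest tie-break; (0, -1, -1) when no positive segment exists."""
    best = (0.0, -1, -1)
    n = len(values)
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            total += values[j]
            if total > best[0]:
                best = (total, i, j)
    return best


def bh_step_up(pvals):
    """Textbook BH: adjusted_(i) = min over j >= i of p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    for rank_index, i in enumerate(order):
        candidates = [
            pvals[order[j]] * m / (j + 1) for j in range(rank_index, m)
        ]
        adjusted[i] = min(min(candidates), 1.0)
    return adjusted


def union_find_components(genes, edges):
    """Single-linkage components by explicit union-find."""
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for g in genes:
        comps.setdefault(find(g), set()).add(g)
    return sorted(tuple(sorted(c)) for c in comps.values())


def tree_path_distances(tree):
    """Leaf-pair path lengths of a dendropy tree as a dict."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out
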