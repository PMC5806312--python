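"""Codon-level building blocks shared by the pairwise Ka/Ks estimator, the
GY94 likelihood engine and the sequence simulator.

Everything here uses the standard genetic code. The 61 sense codons are kept
in a fixed lexicographic order (``SENSE_CODONS``); stop codons are never
valid states.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

AMINO_ACID = {c: _STANDARD.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def single_step_neighbors(codon: str):
    """All codons (sense or stop) one nucleotide away from ``codon``."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append((pos, codon[:pos] + nt + codon[pos + 1 :]))
    return out


@lru_cache(maxsize=1)
def ng86_site_fractions() -> np.ndarray:
    """Per-codon synonymous site counts under the Nei–Gojobori convention.

    For each of the three positions the fraction of possible single-base
    changes that are synonymous is computed, with changes into stop codons
    removed from the set of possible changes; the three fractions are summed.
    Returns an array of length 61 aligned with ``SENSE_CODONS``.
    """
    s = np.zeros(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        total = 0.0
        for pos in range(3):
            syn = 0
            valid = 0
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if is_stop(alt):
                    continue
                valid += 1
                if AMINO_ACID[alt] == AMINO_ACID[codon]:
                    syn += 1
            if valid:
                total += syn / valid
        s[i] = total
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all minimal
    mutational pathways between two sense codons, excluding pathways that
    pass through a stop codon.

    If every pathway passes through a stop, all pathways are used anyway
    (classical fallback; such pairs are vanishingly rare and the alternative
    is an undefined count).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        syn = nonsyn = 0
        current = codon_a
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if AMINO_ACID[nxt] == AMINO_ACID[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:  # all pathways blocked by stops: count through them
        for order in itertools.permutations(diff_pos):
            syn = nonsyn = 0
            current = codon_a
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                same = (not is_stop(nxt)) and AMINO_ACID.get(nxt) == AMINO_ACID.get(
                    current
                )
                if same:
                    syn += 1
                else:
                    nonsyn += 1
                current = nxt
            results.append((syn, nonsyn))
    arr = np.asarray(results, dtype=float)
    mean = arr.mean(axis=0)
    return float(mean[0]), float(mean[1])


@lru_cache(maxsize=1)
def pathway_difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """61x61 tables of pathway-averaged synonymous / nonsynonymous
    difference counts between sense codons."""
    sd = np.zeros((N_SENSE, N_SENSE))
    nd = np.zeros((N_SENSE, N_SENSE))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i < j:
                s, n = _pathway_counts(a, b)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = n
    return sd, nd


def codons_of(seq: str):
    """Split a nucleotide string into codons; length must be a multiple of 3."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(seq: str) -> str:
    """Translate a CDS; raises on internal stop codons."""
    codons = codons_of(seq)
    aas = []
    for k, c in enumerate(codons):
        if is_stop(c):
            if k == len(codons) - 1:
                break
            raise ValueError(f"internal stop codon {c} at codon {k + 1}")
        if c not in AMINO_ACID:
            raise ValueError(f"unrecognized codon {c!r} at codon {k + 1}")
        aas.append(AMINO_ACID[c])
    return "".join(aas)
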