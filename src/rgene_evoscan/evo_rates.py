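"""Codon-aware alignments and Nei–Gojobori (1986) Ka/Ks estimation.

Ka and Ks are estimated per gene pair by the classical NG86 counting
method with the Jukes–Cantor multiple-hit correction:

* per-codon synonymous site fractions (changes to stops excluded),
  S = mean of the two sequences' counts, N = 3*(compared codons) - S;
* synonymous/nonsynonymous differences averaged over all minimal
  mutational pathways between differing codons, pathways through stop
  codons excluded;
* Ks = -(3/4) ln(1 - 4 pS / 3), likewise Ka; proportions >= 3/4 saturate
  and the rate is undefined.

Pairs are labelled paralog (same species) or ortholog (different species);
following the study design only pairs with a defined Ks < 1 are retained
for the rate contrasts.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import (
    CODON_INDEX,
    ng86_site_fractions,
    pathway_difference_tables,
    translate,
)

SATURATION_KS = 1.0


@dataclasses.dataclass
class PairRates:
    gene_a: str
    gene_b: str
    relation: str  # "paralog" | "ortholog"
    ka: float | None
    ks: float | None
    n_codons: int

    @property
    def ka_ks(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0.0:
            return None
        return self.ka / self.ks


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

def backtranslate_alignment(
    protein_alignment: dict[str, str], cds_by_gene: dict[str, str]
) -> dict[str, str]:
    """Expand a protein alignment to a codon alignment using each gene's CDS.

    Every aligned amino acid becomes its source codon; a gap becomes
    ``---``. The CDS must translate exactly to the ungapped protein row
    (a trailing stop codon on the CDS is allowed).
    """
    out = {}
    for gene, prot_row in protein_alignment.items():
        if gene not in cds_by_gene:
            raise KeyError(f"no CDS for {gene}")
        cds = cds_by_gene[gene].upper()
        ungapped = prot_row.replace("-", "")
        translated = translate(cds)
        if translated != ungapped:
            pos = next(
                (i for i, (x, y) in enumerate(zip(translated, ungapped)) if x != y),
                min(len(translated), len(ungapped)),
            )
            raise ValueError(
                f"{gene}: CDS translation does not match protein row at "
                f"residue {pos + 1}"
            )
        codons = iter(
            cds[i : i + 3] for i in range(0, 3 * len(translated), 3)
        )
        row = []
        for aa in prot_row:
            row.append("---" if aa == "-" else next(codons))
        out[gene] = "".join(row)
    return out


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(
    codon_row_a: str,
    codon_row_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    species_a: str | None = None,
    species_b: str | None = None,
) -> PairRates:
    """NG86 Ka/Ks for one pair of aligned codon rows.

    Codon columns where either row carries a gap or ambiguity are dropped
    pairwise. Raises if no codon survives.
    """
    if len(codon_row_a) != len(codon_row_b):
        raise ValueError("rows must come from one alignment (equal length)")
    if len(codon_row_a) % 3:
        raise ValueError("row length must be a multiple of 3")
    site_frac = ng86_site_fractions()
    sd_table, nd_table = pathway_difference_tables()
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(codon_row_a), 3):
        ca = codon_row_a[k : k + 3].upper()
        cb = codon_row_b[k : k + 3].upper()
        ia = CODON_INDEX.get(ca)
        ib = CODON_INDEX.get(cb)
        if ia is None or ib is None:
            continue
        n_codons += 1
        s_a += site_frac[ia]
        s_b += site_frac[ib]
        sd += sd_table[ia, ib]
        nd += nd_table[ia, ib]
    if n_codons == 0:
        raise ValueError(f"{gene_a} vs {gene_b}: no comparable codons")
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    relation = "unknown"
    if species_a is not None and species_b is not None:
        relation = "paralog" if species_a == species_b else "ortholog"
    return PairRates(
        gene_a=gene_a, gene_b=gene_b, relation=relation,
        ka=ka, ks=ks, n_codons=n_codons,
    )


def pairwise_rates(
    codon_alignment: dict[str, str],
    species_of: dict[str, str],
) -> list[PairRates]:
    """NG86 rates for all pairs of one family's codon alignment."""
    out = []
    for a, b in itertools.combinations(sorted(codon_alignment), 2):
        out.append(
            ng86_pair(
                codon_alignment[a],
                codon_alignment[b],
                gene_a=a,
                gene_b=b,
                species_a=species_of.get(a),
                species_b=species_of.get(b),
            )
        )
    return out


def saturation_filter(
    pairs: Iterable[PairRates], ks_cap: float = SATURATION_KS
) -> list[PairRates]:
    """Retain pairs with a defined Ks strictly below ``ks_cap``."""
    return [p for p in pairs if p.ks is not None and p.ks < ks_cap]


# ---------------------------------------------------------------------------
# group summaries and contrasts
# ---------------------------------------------------------------------------

def five_number_summary(values: Sequence[float]) -> dict:
    """Min, Q1 (linear interpolation), median, mean, Q3, max, n."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return {k: float("nan") for k in
                ("min", "q1", "median", "mean", "q3", "max")} | {"n": 0}
    return {
        "min": float(x.min()),
        "q1": float(np.quantile(x, 0.25)),
        "median": float(np.quantile(x, 0.5)),
        "mean": float(x.mean()),
        "q3": float(np.quantile(x, 0.75)),
        "max": float(x.max()),
        "n": int(x.size),
    }


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def group_contrasts(
    pairs_by_group: dict[str, list[PairRates]],
    metric: str = "ks",
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> dict:
    """Box summaries per group plus Welch t-tests between requested pairs.

    ``metric`` is one of ``ka``, ``ks``, ``ka_ks``; undefined values are
    excluded. Ka/Ks output also reports pairs exceeding 1 (candidate
    positive selection).
    """
    values: dict[str, list[float]] = {}
    positive: dict[str, list[tuple[str, str]]] = {}
    for group, pairs in pairs_by_group.items():
        vals = []
        pos = []
        for p in pairs:
            v = getattr(p, metric)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            vals.append(float(v))
            if metric == "ka_ks" and v > 1.0:
                pos.append((p.gene_a, p.gene_b))
        values[group] = vals
        positive[group] = pos
    out: dict = {"metric": metric, "summaries": {}, "tests": []}
    for group, vals in values.items():
        out["summaries"][group] = five_number_summary(vals)
    if contrasts is None:
        contrasts = list(itertools.combinations(sorted(values), 2))
    for a, b in contrasts:
        t, p = welch_test(values.get(a, []), values.get(b, []))
        out["tests"].append({"group_a": a, "group_b": b, "t": t, "p": p})
    if metric == "ka_ks":
        out["pairs_above_one"] = {
            g: {"n": len(pos), "pairs": pos} for g, pos in positive.items()
        }
    return out


def rates_table(pairs: Iterable[PairRates], ks_cap: float = SATURATION_KS) -> pd.DataFrame:
    """Flat per-pair table with the retained flag used downstream."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "relation": p.relation,
                "ka": p.ka if p.ka is not None else float("nan"),
                "ks": p.ks if p.ks is not None else float("nan"),
                "ka_ks": p.ka_ks if p.ka_ks is not None else float("nan"),
                "n_codons": p.n_codons,
                "retained": p.ks is not None and p.ks < ks_cap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "relation", "ka", "ks", "ka_ks",
            "n_codons", "retained",
        ],
    )
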