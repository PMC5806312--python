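"""Candidate merging, NB-ARC+LRR filtering and N-terminal architecture
classification of NBS-LRR genes.

The classification follows the standard two-supergroup taxonomy: genes with
a TIR domain ahead of the NB-ARC are TNLs (one TIR -> TNL', two or more ->
TTNL); the rest are non-TNLs, split by their N-terminal content into CNL'
(coiled-coil), RPW8-CNL (RPW8 then CC), XNL' (no recognized N-terminal
domain) and RPW8-XNL (RPW8 without CC).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_E_THRESHOLD = 1e-4

LETTER_CODES = ("TNL'", "TTNL", "CNL'", "RPW8-CNL", "XNL'", "RPW8-XNL")

GROUP_OF = {
    "TNL'": "TNL",
    "TTNL": "TNL",
    "CNL'": "CNL",
    "RPW8-CNL": "CNL",
    "XNL'": "XNL",
    "RPW8-XNL": "XNL",
}

SUPERGROUP_OF = {code: ("TNL" if grp == "TNL" else "non-TNL")
                 for code, grp in GROUP_OF.items()}


@dataclasses.dataclass(frozen=True)
class DomainHit:
    domain: str
    start: int
    end: int
    e_value: float = 0.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"domain hit start {self.start} > end {self.end}")
        if self.e_value < 0:
            raise ValueError("E-value must be nonnegative")


@dataclasses.dataclass
class DomainAnnotation:
    """Ordered domain hits for one gene (sorted by start)."""

    gene_id: str
    species: str
    hits: list[DomainHit]

    def __post_init__(self):
        self.hits = sorted(self.hits, key=lambda h: (h.start, h.end, h.domain))

    @property
    def domain_order(self) -> list[str]:
        return [h.domain for h in self.hits]


def merge_candidates(
    hits_a: Iterable[tuple[str, float]],
    hits_b: Iterable[str],
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> set[str]:
    """Union of similarity-search hits (E-value filtered) and profile-search
    hits, deduplicated."""
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    bad = []
    kept: set[str] = set()
    for row in hits_a:
        try:
            gene, e = row
        except (TypeError, ValueError):
            bad.append(row)
            continue
        if not isinstance(gene, str) or not gene or not isinstance(e, (int, float)):
            bad.append(row)
            continue
        if e <= e_threshold:
            kept.add(gene)
    for gene in hits_b:
        if not isinstance(gene, str) or not gene:
            bad.append(gene)
            continue
        kept.add(gene)
    if bad:
        raise ValueError(f"malformed candidate rows: {bad!r}")
    return kept


def filter_nbs_lrr(
    candidates: Iterable[str],
    annotations: dict[str, DomainAnnotation],
) -> tuple[set[str], pd.DataFrame]:
    """Keep candidates carrying at least one NB-ARC and one LRR hit.

    Returns (kept set, report of dropped genes naming the missing domain).
    A candidate with no annotation record at all is an error.
    """
    candidates = list(candidates)
    missing = [g for g in candidates if g not in annotations]
    if missing:
        raise KeyError(f"candidates without annotation records: {sorted(missing)}")
    kept = set()
    dropped = []
    for gene in candidates:
        domains = set(annotations[gene].domain_order)
        reasons = []
        if "NB-ARC" not in domains:
            reasons.append("no NB-ARC")
        if "LRR" not in domains:
            reasons.append("no LRR")
        if reasons:
            dropped.append({"gene_id": gene, "reason": "; ".join(reasons)})
        else:
            kept.add(gene)
    return kept, pd.DataFrame(dropped, columns=["gene_id", "reason"])


def classify_architecture(annotation: DomainAnnotation) -> str:
    """Letter code from the domains N-terminal to the first NB-ARC hit.

    Two or more TIRs -> TTNL; one TIR -> TNL'; RPW8 then CC -> RPW8-CNL;
    RPW8 alone -> RPW8-XNL; CC alone -> CNL'; none of TIR/RPW8/CC -> XNL'.
    A TIR co-occurring with RPW8 or CC (a combination outside the published
    taxonomy) classifies by the TIR with a warning.
    """
    order = annotation.domain_order
    if "NB-ARC" not in order:
        raise ValueError(f"{annotation.gene_id}: no NB-ARC hit; run the filter first")
    first_nbarc = next(
        h.start for h in annotation.hits if h.domain == "NB-ARC"
    )
    nterm = [h.domain for h in annotation.hits
             if h.domain != "NB-ARC" and h.start < first_nbarc]
    n_tir = nterm.count("TIR")
    has_rpw8 = "RPW8" in nterm
    has_cc = "CC" in nterm
    if n_tir >= 1:
        if has_rpw8 or has_cc:
            warnings.warn(
                f"{annotation.gene_id}: TIR co-occurs with "
                f"{'RPW8' if has_rpw8 else 'CC'} before NB-ARC; "
                "classifying by the TIR",
                stacklevel=2,
            )
        return "TTNL" if n_tir >= 2 else "TNL'"
    if has_rpw8:
        return "RPW8-CNL" if has_cc else "RPW8-XNL"
    if has_cc:
        return "CNL'"
    return "XNL'"


def classify_all(annotations: dict[str, DomainAnnotation]) -> pd.DataFrame:
    """Classification table: gene_id, species, letter_code, group, supergroup."""
    rows = []
    for gene in sorted(annotations):
        ann = annotations[gene]
        code = classify_architecture(ann)
        rows.append(
            {
                "gene_id": gene,
                "species": ann.species,
                "letter_code": code,
                "group": GROUP_OF[code],
                "supergroup": SUPERGROUP_OF[code],
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "letter_code", "group", "supergroup"]
    )


def tabulate_counts(
    classified: pd.DataFrame, species: Sequence[str] | None = None
) -> pd.DataFrame:
    """Class x species count matrix with group and supergroup subtotals.

    Row layout mirrors the hierarchy: total, TNL (TNL' + TTNL), non-TNL,
    CNL (CNL' + RPW8-CNL), XNL (XNL' + RPW8-XNL), plus each letter code.
    """
    if species is None:
        species = sorted(classified["species"].unique()) if len(classified) else []
    cols = list(species) + ["Total"]
    index = [
        "NBS-LRR", "TNL", "TNL'", "TTNL", "non-TNL",
        "CNL", "CNL'", "RPW8-CNL", "XNL", "XNL'", "RPW8-XNL",
    ]
    table = pd.DataFrame(0, index=index, columns=cols)
    for _, row in classified.iterrows():
        sp = row["species"]
        if sp in table.columns:
            table.loc[row["letter_code"], sp] += 1
    letter = table.loc[list(LETTER_CODES), list(species)].copy()
    table.loc["TNL", list(species)] = letter.loc["TNL'"] + letter.loc["TTNL"]
    table.loc["CNL", list(species)] = letter.loc["CNL'"] + letter.loc["RPW8-CNL"]
    table.loc["XNL", list(species)] = letter.loc["XNL'"] + letter.loc["RPW8-XNL"]
    table.loc["non-TNL", list(species)] = (
        table.loc["CNL", list(species)] + table.loc["XNL", list(species)]
    )
    table.loc["NBS-LRR", list(species)] = (
        table.loc["TNL", list(species)] + table.loc["non-TNL", list(species)]
    )
    table["Total"] = table[list(species)].sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_domain_table(path: str) -> dict[str, DomainAnnotation]:
    """Load a TSV of domain hits (gene_id, species, domain, start, end,
    evalue; extra columns ignored) into per-gene annotations."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species", "domain", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"domain table missing columns: {required - set(df.columns)}")
    out: dict[str, DomainAnnotation] = {}
    for (gene, sp), sub in df.groupby(["gene_id", "species"], sort=False):
        hits = [
            DomainHit(
                domain=str(r["domain"]),
                start=int(r["start"]),
                end=int(r["end"]),
                e_value=float(r.get("evalue", 0.0)) if "evalue" in sub.columns else 0.0,
            )
            for _, r in sub.iterrows()
        ]
        out[str(gene)] = DomainAnnotation(gene_id=str(gene), species=str(sp), hits=hits)
    return out
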