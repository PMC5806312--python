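"""Bundled example data: published per-family summary statistics for the
NBS-LRR gene families of six *Fragaria* genomes.

``load_fragaria_family_table`` gives one row per multi-gene family with its
supergroup (TNL / non-TNL), the family-average Ka/Ks, the single-ratio
model omega (NaN where the family had fewer than three members and was not
estimated), the M7-vs-M8 likelihood-ratio statistic 2Δln with its printed
significance flag, and the number of significant sequence-exchange events.

``load_fragaria_summary`` gives the genome-wide tallies (total genes,
multi-gene counts, paralog exchange-event counts per supergroup).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    path = importlib.resources.files("rgene_evoscan") / "datasets" / name
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_fragaria_family_table() -> pd.DataFrame:
    df = _read("fragaria_nbs_lrr_families.tsv")
    for col in ("ka_ks_mean", "omega_m0", "two_delta_ln"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_fragaria_summary() -> dict[str, int]:
    df = _read("fragaria_nbs_lrr_summary.tsv")
    return dict(zip(df["quantity"], df["value"].astype(int)))
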