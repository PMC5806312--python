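"""End-to-end orchestration of the analysis stages from a single config.

The config is a nested mapping (typically YAML): an input block (paths, or
a ``simulate`` block delegating to the synthetic generator), per-stage
toggles under ``stages``, and thresholds that default to the screen's
standard values (60/60 clustering, Ks < 1 retention, 2Δln critical values
5.991/9.210, 10,000 permutations at P < 0.05, 1 Mb bins, |logFC| >= 2 and
FDR <= 0.05). Every stage appends its summary to one machine-readable
report; a fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np

from . import __version__
from . import (
    evo_rates,
    expression,
    family_cluster,
    gene_conversion,
    hotspots,
    identify_classify,
    phylo,
    synthetic_data,
)
from .selection_models import lrt_m7_m8, fit_m0

DEFAULT_STAGES = (
    "classify",
    "cluster",
    "kaks",
    "clades",
    "selection",
    "geneconv",
    "hotspots",
    "degs",
)

DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "id_threshold": 60.0,
    "cov_threshold": 60.0,
    "ks_cap": 1.0,
    "n_permutations": 10_000,
    "geneconv_alpha": 0.05,
    "bin_size": 1_000_000,
    "hotspot_alpha": 0.05,
    "lfc_threshold": 2.0,
    "fdr_threshold": 0.05,
    "selection_min_members": 3,
    "selection_max_members": 12,
}


def run_pipeline(config: dict, outdir: str | None = None) -> dict:
    """Execute the enabled stages on simulated (or supplied) data.

    Returns the run report; writes ``report.json`` plus per-stage tables
    when ``outdir`` is given. A stage failure raises with the stage named.
    """
    cfg = {**DEFAULTS, **{k: v for k, v in config.items() if k != "stages"}}
    stages = (
        list(config["stages"]) if "stages" in config else list(DEFAULT_STAGES)
    )
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg["seed"],
        "parameters": {k: cfg[k] for k in DEFAULTS},
        "stages": {},
    }
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    sim_cfg = synthetic_data.SimulationConfig(
        seed=int(cfg["seed"]), **config.get("simulate", {})
    )
    families = synthetic_data.simulate_families(sim_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg["seed"]), 1009]))
    genes = [
        (g, fam.species[g]) for fam in families for g in sorted(fam.sequences)
    ]
    species_of = {g: sp for g, sp in genes}
    sequences = {g: fam.sequences[g] for fam in families for g in fam.sequences}

    current = "setup"
    try:
        domains = synthetic_data.assign_architectures(genes, rng)
        annotations = {}
        for gene, sub in domains.groupby("gene_id", sort=False):
            hits = [
                identify_classify.DomainHit(
                    domain=r["domain"], start=int(r["start"]),
                    end=int(r["end"]), e_value=float(r["evalue"]),
                )
                for _, r in sub.iterrows()
            ]
            annotations[gene] = identify_classify.DomainAnnotation(
                gene_id=gene, species=species_of[gene], hits=hits
            )

        if "classify" in stages:
            current = "classify"
            classified = identify_classify.classify_all(annotations)
            table = identify_classify.tabulate_counts(classified)
            report["stages"]["classify"] = {
                "n_genes": int(len(classified)),
                "counts_total": {
                    k: int(v) for k, v in table["Total"].items()
                },
            }
            if outdir:
                classified.to_csv(
                    os.path.join(outdir, "classification.tsv"), sep="\t", index=False
                )
        else:
            classified = identify_classify.classify_all(annotations)

        supergroup_of = dict(
            zip(classified["gene_id"], classified["supergroup"])
        )

        # the true simulated families are the clustering units downstream
        fam_members = {f.family_id: sorted(f.sequences) for f in families}

        if "cluster" in stages:
            current = "cluster"
            fams, singles, _sims = family_cluster.cluster_by_supergroup(
                sequences, supergroup_of,
                cfg["id_threshold"], cfg["cov_threshold"],
            )
            n_multi = sum(len(f.members) for f in fams)
            total = n_multi + len(singles)
            report["stages"]["cluster"] = {
                "n_families": len(fams),
                "n_multi_gene": n_multi,
                "n_singletons": len(singles),
                "proportion_multi_gene_pct": (
                    family_cluster.multi_gene_proportion(n_multi, total)
                    if total else float("nan")
                ),
            }

        if "kaks" in stages:
            current = "kaks"
            by_rel: dict[str, list] = {"paralog": [], "ortholog": []}
            for fam in families:
                pairs = evo_rates.pairwise_rates(fam.sequences, fam.species)
                for p in evo_rates.saturation_filter(pairs, cfg["ks_cap"]):
                    by_rel[p.relation].append(p)
            contrast = evo_rates.group_contrasts(by_rel, metric="ks")
            report["stages"]["kaks"] = {
                "n_paralog_pairs": len(by_rel["paralog"]),
                "n_ortholog_pairs": len(by_rel["ortholog"]),
                "ks_summary": contrast["summaries"],
                "ks_tests": contrast["tests"],
            }

        if "clades" in stages:
            current = "clades"
            totals = {"n_lineage_specific": 0, "n_species_specific": 0}
            for fam in families:
                if len(fam.sequences) < 3:
                    continue
                tree = phylo.nj_tree(fam.sequences)
                labels = phylo.label_duplication_clades(
                    phylo.midpoint_root(tree)
                )
                summary = phylo.clade_type_summary(labels)
                totals["n_lineage_specific"] += summary["n_lineage_specific"]
                totals["n_species_specific"] += summary["n_species_specific"]
            report["stages"]["clades"] = totals

        if "selection" in stages:
            current = "selection"
            rows = []
            for fam in families:
                n = len(fam.sequences)
                if not (
                    cfg["selection_min_members"] <= n <= cfg["selection_max_members"]
                ):
                    continue
                tree = phylo.nj_tree(fam.sequences)
                m0 = fit_m0(fam.sequences, tree)
                res = lrt_m7_m8(fam.sequences, tree, family_id=fam.family_id)
                rows.append(
                    {
                        "family_id": fam.family_id,
                        "omega_m0": m0.params["omega"],
                        "two_delta_ln": res.two_delta_ln,
                        "tier": res.tier,
                        "n_positive_sites": len(res.positive_sites),
                    }
                )
            n_sig = sum(1 for r in rows if r["tier"] in ("*", "**"))
            report["stages"]["selection"] = {
                "n_families_tested": len(rows),
                "n_significant": n_sig,
                "families": rows,
            }

        if "geneconv" in stages:
            current = "geneconv"
            all_events = []
            for fam in families:
                if len(fam.sequences) < 2:
                    continue
                all_events.extend(
                    gene_conversion.permutation_test(
                        fam.sequences,
                        family_id=fam.family_id,
                        species_of=fam.species,
                        n_permutations=int(cfg["n_permutations"]),
                        alpha=cfg["geneconv_alpha"],
                        seed=int(cfg["seed"]),
                    )
                )
            report["stages"]["geneconv"] = gene_conversion.classify_events(
                all_events
            )

        if "hotspots" in stages:
            current = "hotspots"
            coords, planted = synthetic_data.place_on_chromosomes(
                genes, sim_cfg, rng
            )
            lengths = {
                f"chr{c}": sim_cfg.chromosome_length
                for c in range(1, sim_cfg.n_chromosomes + 1)
            }
            binned = hotspots.bin_genes(coords, lengths, cfg["bin_size"])
            calls = hotspots.detect_hotspots(binned, alpha=cfg["hotspot_alpha"])
            flagged = calls[calls["hotspot"]]
            report["stages"]["hotspots"] = {
                "n_hotspot_bins": int(len(flagged)),
                "planted_bins": [[c, b] for c, b in planted],
                "flagged_bins": [
                    [int(r["chrom"].replace("chr", "")), int(r["bin"])]
                    for _, r in flagged.iterrows()
                ],
            }

        if "degs" in stages:
            current = "degs"
            counts, truth = synthetic_data.simulate_expression(
                [g for g, _ in genes], sim_cfg, rng
            )
            control = [c for c in counts.columns if c.startswith("T0_")]
            infected = [c for c in counts.columns if not c.startswith("T0_")]
            _table, degs = expression.de_screen(
                counts, control, infected, contrast="control_vs_infected",
                lfc_threshold=cfg["lfc_threshold"],
                fdr_threshold=cfg["fdr_threshold"],
            )
            true_de = set(truth[truth["is_de"]]["gene_id"])
            called = {d.gene_id for d in degs}
            report["stages"]["degs"] = {
                "n_degs": len(degs),
                "n_true_de": len(true_de),
                "recall": (
                    len(called & true_de) / len(true_de) if true_de else float("nan")
                ),
            }
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    report["n_families_simulated"] = len(families)
    report["n_genes"] = len(genes)
    if outdir:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
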