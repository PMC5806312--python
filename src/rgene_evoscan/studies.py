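"""Seeded simulation studies validating the estimators end to end.

Each study generates data with the synthetic generator, runs the relevant
pipeline stage, and reports recovery/error statistics against the planted
truth. They are the package's calibration experiments: parameter recovery
of the single-ratio codon model, type-I control and power of the M7-vs-M8
test, the paralog-versus-ortholog Ks contrast produced by pre-speciation
duplication, shared-hotspot recovery, gene-conversion detection power, and
the differential-expression screen's operating characteristics.

Problem sizes are chosen so every study runs in minutes on one core; the
replicate counts are part of each study's definition.
"""

from __future__ import annotations

import numpy as np

from . import evo_rates, expression, gene_conversion, hotspots, phylo
from . import synthetic_data as sd
from .selection_models import beta_class_omegas, fit_m0, lrt_m7_m8


def _spawn(seed: int, label: int, n: int):
    return np.random.SeedSequence([int(seed), int(label)]).spawn(n)


def ng86_recovery_study(
    seed: int = 1,
    n_replicates: int = 50,
    n_codons: int = 500,
    ks_true: float = 0.3,
    omega_true: float = 0.2,
    kappa: float = 1.0,
) -> dict:
    """Pairwise NG86 estimates against the generating Ks and omega.

    kappa defaults to 1 because the NG86 counting scheme weighs all
    single-base changes equally; under transition bias the method's
    classical downward Ka/Ks bias appears and is reported, not hidden.
    """
    ks_vals, ratio_vals = [], []
    for stream in _spawn(seed, 11, n_replicates):
        rng = np.random.default_rng(stream)
        a, b = sd.simulate_codon_pair(n_codons, ks_true, omega_true, kappa, rng)
        pair = evo_rates.ng86_pair(a, b)
        if pair.ks is not None:
            ks_vals.append(pair.ks)
        if pair.ka_ks is not None:
            ratio_vals.append(pair.ka_ks)
    return {
        "n": n_replicates,
        "ks_true": ks_true,
        "omega_true": omega_true,
        "mean_ks": float(np.mean(ks_vals)),
        "mean_ka_ks": float(np.mean(ratio_vals)),
        "ks_error": float(abs(np.mean(ks_vals) - ks_true)),
        "ka_ks_error": float(abs(np.mean(ratio_vals) - omega_true)),
    }


def m0_recovery_study(
    seed: int = 1,
    n_replicates: int = 20,
    n_codons: int = 300,
    omega_true: float = 0.2,
    kappa: float = 2.0,
) -> dict:
    """Single-ratio model fit on six-taxon alignments simulated at a known
    omega; reports the mean estimate and its absolute error."""
    tree = sd.fragaria_species_tree()
    estimates = []
    for stream in _spawn(seed, 23, n_replicates):
        rng = np.random.default_rng(stream)
        seqs = sd.simulate_alignment(tree, n_codons, kappa, omega_true, rng)
        fit = fit_m0(seqs, phylo.nj_tree(seqs))
        estimates.append(fit.params["omega"])
    mean = float(np.mean(estimates))
    return {
        "n": n_replicates,
        "omega_true": omega_true,
        "mean_omega": mean,
        "abs_error": float(abs(mean - omega_true)),
    }


def m7m8_type_i_study(
    seed: int = 1,
    n_replicates: int = 50,
    n_codons: int = 100,
    kappa: float = 2.0,
) -> dict:
    """Rejection rate of the M7-vs-M8 test on data simulated under M7
    (no positive selection), small four-taxon alignments."""
    import dendropy

    tree = dendropy.Tree.get(
        data="((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);", schema="newick"
    )
    rejections = 0
    for stream in _spawn(seed, 31, n_replicates):
        rng = np.random.default_rng(stream)
        cats = beta_class_omegas(0.5, 1.5, 10)
        site_omegas = cats[rng.integers(0, len(cats), n_codons)]
        seqs = sd.simulate_alignment(tree, n_codons, kappa, site_omegas, rng)
        result = lrt_m7_m8(seqs, tree)
        if result.tier in ("*", "**"):
            rejections += 1
    return {
        "n": n_replicates,
        "nominal_alpha": 0.05,
        "rejection_rate": rejections / n_replicates,
    }


def m8_power_study(
    seed: int = 1,
    n_replicates: int = 20,
    n_codons: int = 300,
    p1: float = 0.2,
    omega_s: float = 3.0,
    kappa: float = 2.0,
) -> dict:
    """Fraction of highly significant ("**") calls on data carrying a
    genuine positive-selection class (proportion p1 at omega_s).

    Uses the six-species topology at a deeper calibration (terminal 0.15,
    internal 0.10 on the Ks scale) so alignments hold enough substitutions
    for the site-model contrast to be identifiable.
    """
    tree = sd.fragaria_species_tree(terminal_length=0.15, internal_length=0.10)
    strong = 0
    for stream in _spawn(seed, 37, n_replicates):
        rng = np.random.default_rng(stream)
        cats = beta_class_omegas(0.5, 1.5, 10)
        site_omegas = cats[rng.integers(0, len(cats), n_codons)]
        site_omegas = np.where(rng.random(n_codons) < p1, omega_s, site_omegas)
        seqs = sd.simulate_alignment(tree, n_codons, kappa, site_omegas, rng)
        result = lrt_m7_m8(seqs, phylo.nj_tree(seqs))
        if result.tier == "**":
            strong += 1
    return {"n": n_replicates, "power": strong / n_replicates}


def ks_contrast_study(
    seed: int = 1,
    n_families: int = 8,
    stem_length: float = 0.3,
) -> dict:
    """The headline evolutionary pattern: families duplicated before
    speciation give paralog pairs (tracing back to the old duplication)
    larger Ks than same-lineage ortholog pairs."""
    by_rel: dict[str, list[float]] = {"paralog": [], "ortholog": []}
    for k, stream in enumerate(_spawn(seed, 41, n_families)):
        cfg = sd.SimulationConfig(
            seed=seed,
            n_pre_duplications=1,
            n_post_duplications=1,
            stem_length=stem_length,
        )
        fam = sd.simulate_family(
            cfg, family_id=f"fam{k}", rng=np.random.default_rng(stream)
        )
        pairs = evo_rates.pairwise_rates(fam.sequences, fam.species)
        for p in evo_rates.saturation_filter(pairs):
            by_rel[p.relation].append(p.ks)
    from .family_cluster import compare_identity_groups

    test = compare_identity_groups(by_rel["paralog"], by_rel["ortholog"])
    return {
        "n_paralog_pairs": len(by_rel["paralog"]),
        "n_ortholog_pairs": len(by_rel["ortholog"]),
        "mean_paralog_ks": test["mean_a"],
        "mean_ortholog_ks": test["mean_b"],
        "t": test["t"],
        "p": test["p"],
    }


def hotspot_recovery_study(
    seed: int = 1,
    n_genes_per_species: int = 60,
    enrichment: float = 10.0,
    n_hotspot_bins: int = 3,
) -> dict:
    """Planted shared hotspot bins recovered by the Duncan screen."""
    cfg = sd.SimulationConfig(
        seed=seed,
        hotspot_enrichment=enrichment,
        n_hotspot_bins=n_hotspot_bins,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))
    genes = [
        (f"g{i}_{sp}", sp)
        for i in range(n_genes_per_species)
        for sp in sd.SPECIES
    ]
    coords, planted = sd.place_on_chromosomes(genes, cfg, rng)
    lengths = {
        f"chr{c}": cfg.chromosome_length
        for c in range(1, cfg.n_chromosomes + 1)
    }
    calls = hotspots.detect_hotspots(
        hotspots.bin_genes(coords, lengths, cfg.bin_size)
    )
    flagged = {
        (int(r["chrom"].removeprefix("chr")), int(r["bin"]))
        for _, r in calls[calls["hotspot"]].iterrows()
    }
    found = sum(1 for p in planted if p in flagged)
    return {
        "n_planted": len(planted),
        "n_detected": found,
        "detected_fraction": found / len(planted),
        "n_flagged_total": len(flagged),
    }


def conversion_power_study(
    seed: int = 1,
    n_replicates: int = 20,
    n_permutations: int = 1000,
    tract_fraction: float = 0.4,
) -> dict:
    """Power to detect a planted conversion tract (a copy of 40% of one
    paralog pasted into another) at the family-wise permutation test."""
    detected = 0
    for k, stream in enumerate(_spawn(seed, 47, n_replicates)):
        rng = np.random.default_rng(stream)
        cfg = sd.SimulationConfig(
            seed=seed, n_pre_duplications=1, n_post_duplications=0,
            stem_length=0.5,
        )
        fam = sd.simulate_family(cfg, family_id=f"fam{k}", rng=rng)
        seqs = dict(fam.sequences)
        names = sorted(seqs)
        donor, acceptor = names[0], names[1]
        cut = int(len(seqs[donor]) * tract_fraction) // 3 * 3
        seqs[acceptor] = seqs[donor][:cut] + seqs[acceptor][cut:]
        events = gene_conversion.permutation_test(
            seqs,
            family_id=fam.family_id,
            species_of=fam.species,
            n_permutations=n_permutations,
            seed=int(stream.generate_state(1)[0] % (2**31)),
        )
        if any({e.gene_a, e.gene_b} == {donor, acceptor} for e in events):
            detected += 1
    return {"n": n_replicates, "power": detected / n_replicates}


def conversion_null_study(
    seed: int = 1,
    n_replicates: int = 50,
    n_permutations: int = 500,
) -> dict:
    """False-event rate on families with no sequence exchange."""
    false_families = 0
    for k, stream in enumerate(_spawn(seed, 53, n_replicates)):
        rng = np.random.default_rng(stream)
        cfg = sd.SimulationConfig(
            seed=seed, n_pre_duplications=1, n_post_duplications=0,
            stem_length=0.5,
        )
        fam = sd.simulate_family(cfg, family_id=f"fam{k}", rng=rng)
        events = gene_conversion.permutation_test(
            fam.sequences,
            species_of=fam.species,
            n_permutations=n_permutations,
            seed=int(stream.generate_state(1)[0] % (2**31)),
        )
        if events:
            false_families += 1
    return {"n": n_replicates, "false_rate": false_families / n_replicates}


def de_screen_study(
    seed: int = 1,
    n_genes: int = 300,
    n_replicates: int = 20,
) -> dict:
    """Recall on planted DE genes and the false-flag rate under a null.

    Power arm: effect 4 log2 units, dispersion 0.1, 3 vs 3 samples.
    Null arm: de_fraction 0 with the same design; the false rate is the
    fraction of genes flagged at the |logFC| >= 2, FDR <= 0.05 screen.
    """
    recalls, false_rates = [], []
    for stream in _spawn(seed, 59, n_replicates):
        rng = np.random.default_rng(stream)
        for arm, de_fraction in (("power", 0.2), ("null", 0.0)):
            cfg = sd.SimulationConfig(
                seed=seed, de_fraction=de_fraction, log2_effect=4.0,
                dispersion=0.1, n_samples_per_condition=3,
            )
            counts, truth = sd.simulate_expression(
                [f"g{i}" for i in range(n_genes)], cfg, rng
            )
            control = [c for c in counts.columns if c.startswith("T0_")]
            infected = [c for c in counts.columns if not c.startswith("T0_")]
            _, degs = expression.de_screen(counts, control, infected)
            called = {d.gene_id for d in degs}
            if arm == "power":
                true_de = set(truth[truth["is_de"]]["gene_id"])
                if true_de:
                    recalls.append(len(called & true_de) / len(true_de))
            else:
                false_rates.append(len(called) / n_genes)
    return {
        "n": n_replicates,
        "recall": float(np.mean(recalls)),
        "false_rate": float(np.mean(false_rates)),
    }
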