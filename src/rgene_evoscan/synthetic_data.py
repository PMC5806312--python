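"""Synthetic multi-species resistance-gene-family generator.

Emulates the structure of an NBS-LRR gene-family dataset from six closely
related strawberry (*Fragaria*) genomes, with known ground truth for every
downstream stage:

* a six-species tree with Ks-scale branch lengths;
* gene families whose duplications are planted either on the root edge
  (*pre-speciation* — every duplicate lineage then carries one ortholog per
  species) or on terminal edges (*post-speciation* — within-species
  paralogs);
* codon sequences evolved under a GY94 process (transition/transversion
  ratio kappa, dN/dS regime omega — a single value or a beta site mixture
  with an optional positive-selection class), branch lengths expressed as
  expected synonymous substitutions per synonymous site;
* domain architectures drawn from the six observed N-terminal layouts;
* chromosome placements with planted, cross-species *shared* hotspot bins;
* negative-binomial expression tables with planted differential expression
  between control and infected samples.

All randomness flows from one seed through per-family child streams, so
any family can be regenerated independently and the whole dataset is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._codons import N_SENSE, SENSE_CODONS, translate
from .selection_models import (
    TransitionKernel,
    beta_class_omegas,
    gy94_generator,
    uniform_codon_frequencies,
)

SPECIES = (
    "F_ananassa",
    "F_iinumae",
    "F_nipponica",
    "F_nubicola",
    "F_orientalis",
    "F_vesca",
)

#: Default architecture frequencies, proportional to the published
#: per-class totals across the six genomes (1134 genes).
ARCHITECTURE_CLASS_COUNTS = {
    "TNL'": 223,
    "TTNL": 24,
    "CNL'": 265,
    "RPW8-CNL": 27,
    "XNL'": 572,
    "RPW8-XNL": 23,
}

ARCHITECTURE_LAYOUT = {
    "TNL'": ("TIR", "NB-ARC", "LRR"),
    "TTNL": ("TIR", "TIR", "NB-ARC", "LRR"),
    "CNL'": ("CC", "NB-ARC", "LRR"),
    "RPW8-CNL": ("RPW8", "CC", "NB-ARC", "LRR"),
    "XNL'": ("NB-ARC", "LRR"),
    "RPW8-XNL": ("RPW8", "NB-ARC", "LRR"),
}

_DOMAIN_LENGTH = {"TIR": 170, "RPW8": 100, "CC": 60, "NB-ARC": 280, "LRR": 300}


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    Branch-length quantities are on the Ks scale (expected synonymous
    substitutions per synonymous site). ``omega_beta``/``omega_positive``
    switch the selection regime from a single dN/dS to a beta site mixture
    (optionally plus a class with omega_s > 1 and proportion p1).
    """

    seed: int = 0
    n_families: int = 20
    genes_per_species_range: tuple[int, int] = (1, 1)  # via duplication counts
    n_pre_duplications: int = 2
    n_post_duplications: int = 1
    kappa: float = 2.0
    omega: float = 0.2
    omega_beta: tuple[float, float] | None = None
    omega_positive: tuple[float, float] | None = None  # (p1, omega_s)
    n_codons: int = 300
    stem_length: float = 0.3
    saturation_cap: float = 3.0
    loss_probability: float = 0.0
    pre_duplication_edge: str = "root"
    # chromosome placement
    n_chromosomes: int = 7
    chromosome_length: int = 25_000_000
    bin_size: int = 1_000_000
    n_hotspot_bins: int = 3
    hotspot_enrichment: float = 10.0
    # expression
    n_samples_per_condition: int = 3
    de_fraction: float = 0.2
    log2_effect: float = 4.0
    dispersion: float = 0.1
    base_mean: float = 100.0

    def __post_init__(self):
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.loss_probability <= 1.0:
            raise ValueError("loss_probability must be in [0, 1]")
        for name in ("kappa", "omega", "stem_length", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_samples_per_condition < 1:
            raise ValueError("need at least one sample per condition")
        if self.chromosome_length <= self.bin_size:
            raise ValueError("chromosome length must exceed bin size")


@dataclasses.dataclass
class SimulatedFamily:
    """One simulated gene family with its ground truth."""

    family_id: str
    sequences: dict[str, str]  # gene -> codon string (gap-free)
    tree: dendropy.Tree  # true gene tree, duplication nodes annotated
    species: dict[str, str]  # gene -> species
    site_omegas: np.ndarray  # true per-site dN/dS
    duplications: list[dict]  # timing, species set per duplication node
    architecture: dict[str, str] = dataclasses.field(default_factory=dict)


def fragaria_species_tree(
    terminal_length: float = 0.03, internal_length: float = 0.02
) -> dendropy.Tree:
    """Default six-species tree (Ks-scale branch lengths).

    The cultivated octoploid groups with its woodland progenitor
    *F. vesca*; the remaining wild species form the sister groups.
    """
    newick = (
        "(((F_vesca:{t},F_ananassa:{t}):{i},(F_nubicola:{t},F_orientalis:{t}):{i})"
        ":{i},(F_iinumae:{t},F_nipponica:{t}):{i2});"
    ).format(t=terminal_length, i=internal_length, i2=internal_length * 2)
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _site_classes(config: SimulationConfig, rng: np.random.Generator, n_codons: int):
    """Per-site true omega values under the configured regime."""
    if config.omega_beta is None:
        return np.full(n_codons, float(config.omega))
    p, q = config.omega_beta
    cats = beta_class_omegas(p, q, 10)
    omegas = cats[rng.integers(0, len(cats), size=n_codons)]
    if config.omega_positive is not None:
        p1, omega_s = config.omega_positive
        hot = rng.random(n_codons) < p1
        omegas = np.where(hot, omega_s, omegas)
    return omegas


def _kernels_for(omegas: np.ndarray, kappa: float) -> dict[float, TransitionKernel]:
    pi = uniform_codon_frequencies()
    return {
        w: TransitionKernel(gy94_generator(kappa, w, pi=pi, scale="synonymous"), pi)
        for w in np.unique(omegas)
    }


def _evolve(
    parent_states: np.ndarray,
    t: float,
    omegas: np.ndarray,
    kernels: dict[float, TransitionKernel],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw child codon states from P(t), sitewise by omega class."""
    child = parent_states.copy()
    if t <= 0:
        return child
    for w, kernel in kernels.items():
        sites = np.nonzero(omegas == w)[0]
        if sites.size == 0:
            continue
        cum = np.cumsum(kernel.probability(t), axis=1)
        u = rng.random(sites.size)
        rows = cum[parent_states[sites]]
        child[sites] = (rows < u[:, None]).sum(axis=1)
    return child


def simulate_alignment(
    tree: dendropy.Tree,
    n_codons: int,
    kappa: float,
    site_omegas: np.ndarray | float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve gap-free codon sequences down ``tree`` (Ks-scale lengths).

    Returns leaf-label -> codon string; no internal stop codons can occur
    because stop states are outside the chain's state space.
    """
    omegas = (
        np.full(n_codons, float(site_omegas))
        if np.isscalar(site_omegas)
        else np.asarray(site_omegas, dtype=float)
    )
    kernels = _kernels_for(omegas, kappa)
    root_states = rng.integers(0, N_SENSE, size=n_codons)
    states = {tree.seed_node: root_states}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            t = node.edge.length or 0.0
            states[node] = _evolve(states[node.parent_node], t, omegas, kernels, rng)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            out[label] = "".join(SENSE_CODONS[i] for i in states[node])
    return out


def simulate_codon_pair(
    n_codons: int,
    ks_distance: float,
    omega: float,
    kappa: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """A sequence and its descendant after ``ks_distance`` expected
    synonymous substitutions per synonymous site."""
    if rng is None:
        rng = np.random.default_rng(0)
    omegas = np.full(n_codons, float(omega))
    kernels = _kernels_for(omegas, kappa)
    a = rng.integers(0, N_SENSE, size=n_codons)
    b = _evolve(a, ks_distance, omegas, kernels, rng)
    join = lambda s: "".join(SENSE_CODONS[i] for i in s)
    return join(a), join(b)


# ---------------------------------------------------------------------------
# gene-tree construction
# ---------------------------------------------------------------------------

def _copy_species_subtree(species_tree, taxa, suffix, stem):
    """A clone of the species tree with leaves renamed species|gene."""
    def clone(node):
        new = dendropy.Node()
        new.edge.length = node.edge.length
        if node.is_leaf():
            sp = node.taxon.label
            new.taxon = taxa.require_taxon(f"{sp}|{suffix}_{sp}")
        for child in node.child_nodes():
            new.add_child(clone(child))
        return new

    top = clone(species_tree.seed_node)
    top.edge.length = stem
    return top


def build_gene_tree(
    species_tree: dendropy.Tree,
    family_id: str,
    n_pre: int,
    n_post: int,
    stem_length: float,
    rng: np.random.Generator,
) -> tuple[dendropy.Tree, list[dict]]:
    """Graft duplications onto the species tree.

    Pre-speciation duplications sit on the root (stem) edge as a chain of
    binary duplication nodes, so each of the ``n_pre + 1`` duplicate
    lineages is a complete species-tree copy. Post-speciation duplications
    split random terminal edges, duplicating a single gene within one
    species.
    """
    taxa = dendropy.TaxonNamespace()
    duplications: list[dict] = []
    n_copies = n_pre + 1
    spacing = stem_length / n_copies
    species = sorted(t.label for t in species_tree.taxon_namespace)

    copies = [
        _copy_species_subtree(
            species_tree, taxa, f"{family_id}c{k}", stem_length - k * spacing
        )
        for k in range(n_copies)
    ]
    root = copies[0]
    if n_pre > 0:
        prev = None
        for k in range(n_pre):
            dup = dendropy.Node()
            dup.edge.length = spacing if k > 0 else 0.0
            dup.is_duplication = True
            dup.timing = "pre"
            dup.add_child(copies[k])
            copies[k].edge.length = stem_length - k * spacing
            if prev is None:
                root = dup
            else:
                prev.add_child(dup)
            prev = dup
            duplications.append({"timing": "pre", "species": set(species)})
        # the last copy hangs off the deepest duplication node; its edge
        # must restore the same root-to-species-root depth as its siblings
        prev.add_child(copies[n_pre])
        copies[n_pre].edge.length = stem_length - (n_pre - 1) * spacing

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True

    for j in range(n_post):
        leaves = tree.leaf_nodes()
        target = leaves[int(rng.integers(0, len(leaves)))]
        sp = target.taxon.label.split("|", 1)[0]
        length = target.edge.length or 0.0
        u = float(rng.uniform(0.25, 0.75))
        parent = target.parent_node
        dup = dendropy.Node()
        dup.edge.length = length * u
        dup.is_duplication = True
        dup.timing = "post"
        parent.remove_child(target)
        parent.add_child(dup)
        target.edge.length = length * (1 - u)
        twin = dendropy.Node(
            taxon=taxa.require_taxon(f"{sp}|{family_id}p{j}_{sp}")
        )
        twin.edge.length = length * (1 - u)
        dup.add_child(target)
        dup.add_child(twin)
        duplications.append({"timing": "post", "species": {sp}})
    return tree, duplications


def _max_root_to_tip(tree: dendropy.Tree) -> float:
    best = 0.0
    depth = {tree.seed_node: tree.seed_node.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            best = max(best, depth[node])
    return best


def simulate_family(
    config: SimulationConfig,
    species_tree: dendropy.Tree | None = None,
    family_id: str = "fam0",
    rng: np.random.Generator | None = None,
) -> SimulatedFamily:
    """Simulate one gene family: tree grafting, optional loss, codon
    evolution, ground-truth bookkeeping."""
    if species_tree is None:
        species_tree = fragaria_species_tree()
    if len(species_tree.leaf_nodes()) < 2:
        raise ValueError("species tree must have at least 2 leaves")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    tree, duplications = build_gene_tree(
        species_tree,
        family_id,
        config.n_pre_duplications,
        config.n_post_duplications,
        config.stem_length,
        rng,
    )
    if _max_root_to_tip(tree) > config.saturation_cap:
        raise ValueError(
            "expected divergence exceeds the saturation cap "
            f"({config.saturation_cap} on the Ks scale)"
        )
    if config.loss_probability > 0:
        for leaf in list(tree.leaf_nodes()):
            if len(tree.leaf_nodes()) <= 2:
                break
            if rng.random() < config.loss_probability:
                tree.prune_taxa([leaf.taxon])
    site_omegas = _site_classes(config, rng, config.n_codons)
    sequences = simulate_alignment(
        tree, config.n_codons, config.kappa, site_omegas, rng
    )
    species = {g: g.split("|", 1)[0] for g in sequences}
    return SimulatedFamily(
        family_id=family_id,
        sequences=sequences,
        tree=tree,
        species=species,
        site_omegas=site_omegas,
        duplications=duplications,
    )


def simulate_families(
    config: SimulationConfig, species_tree: dendropy.Tree | None = None
) -> list[SimulatedFamily]:
    """Independently reproducible families from one master seed."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_families)
    return [
        simulate_family(
            config,
            species_tree,
            family_id=f"fam{k}",
            rng=np.random.default_rng(streams[k]),
        )
        for k in range(config.n_families)
    ]


# ---------------------------------------------------------------------------
# domain architectures
# ---------------------------------------------------------------------------

def default_architecture_frequencies() -> dict[str, float]:
    total = sum(ARCHITECTURE_CLASS_COUNTS.values())
    return {k: v / total for k, v in ARCHITECTURE_CLASS_COUNTS.items()}


def assign_architectures(
    genes: Iterable[tuple[str, str]],
    rng: np.random.Generator,
    frequencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw one domain architecture per gene and emit an annotation table.

    ``genes`` is an iterable of (gene_id, species). Domain positions are
    consecutive non-overlapping amino-acid intervals with small random
    spacing; E-values are sampled log-uniformly below 1e-5.
    """
    if frequencies is None:
        frequencies = default_architecture_frequencies()
    classes = sorted(frequencies)
    probs = np.array([frequencies[c] for c in classes], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("architecture frequencies must have positive mass")
    probs = probs / probs.sum()
    rows = []
    for gene_id, sp in genes:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        pos = 1
        for domain in ARCHITECTURE_LAYOUT[cls]:
            length = _DOMAIN_LENGTH[domain] + int(rng.integers(-10, 11))
            start = pos + int(rng.integers(1, 15))
            end = start + length - 1
            pos = end + 1
            rows.append(
                {
                    "gene_id": gene_id,
                    "species": sp,
                    "domain": domain,
                    "start": start,
                    "end": end,
                    "evalue": float(10.0 ** -rng.uniform(5, 50)),
                    "architecture_class": cls,
                }
            )
    columns = ["gene_id", "species", "domain", "start", "end", "evalue",
               "architecture_class"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# chromosome placement
# ---------------------------------------------------------------------------

def choose_hotspot_bins(config: SimulationConfig, rng: np.random.Generator):
    """Pick the planted hotspot (chromosome, bin) pairs, shared by all
    species."""
    n_bins = config.chromosome_length // config.bin_size
    pairs = [(c, b) for c in range(1, config.n_chromosomes + 1) for b in range(n_bins)]
    idx = rng.choice(len(pairs), size=config.n_hotspot_bins, replace=False)
    return sorted(pairs[i] for i in idx)


def place_on_chromosomes(
    genes: Iterable[tuple[str, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
    hotspot_bins: Sequence[tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Place genes on chromosomes; planted hotspot bins receive
    enrichment-fold higher density in every species (shared hotspots).

    Returns a BED-like table (chrom, start, end, gene_id, species; 0-based
    half-open) and the hotspot bins used.
    """
    if config.chromosome_length <= config.bin_size:
        raise ValueError("chromosome length must exceed bin size")
    if hotspot_bins is None:
        hotspot_bins = choose_hotspot_bins(config, rng)
    hot = set(hotspot_bins)
    n_bins = config.chromosome_length // config.bin_size
    pairs = [(c, b) for c in range(1, config.n_chromosomes + 1) for b in range(n_bins)]
    weights = np.array(
        [config.hotspot_enrichment if p in hot else 1.0 for p in pairs]
    )
    weights = weights / weights.sum()
    rows = []
    genes = list(genes)
    if genes:
        picks = rng.choice(len(pairs), size=len(genes), p=weights)
        for (gene_id, sp), k in zip(genes, picks):
            chrom, b = pairs[k]
            start = b * config.bin_size + int(
                rng.integers(0, config.bin_size - 3000)
            )
            rows.append(
                {
                    "chrom": f"chr{chrom}",
                    "start": start,
                    "end": start + 3000,
                    "gene_id": gene_id,
                    "species": sp,
                }
            )
    columns = ["chrom", "start", "end", "gene_id", "species"]
    return pd.DataFrame(rows, columns=columns), list(hotspot_bins)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    timepoints: Sequence[str] = ("0", "1dai"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted DE genes.

    The first timepoint is the control; DE genes shift every later
    timepoint by ``log2_effect`` (up or down at random). Counts are drawn
    Gamma–Poisson with the configured dispersion (var = mu + disp * mu^2).
    Returns (counts genes x samples, truth table).
    """
    n = len(gene_ids)
    base = rng.lognormal(mean=np.log(config.base_mean), sigma=0.6, size=n)
    is_de = rng.random(n) < config.de_fraction
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    direction[~is_de] = 0.0
    samples = []
    means = []
    for t_i, tp in enumerate(timepoints):
        for r in range(config.n_samples_per_condition):
            samples.append(f"T{tp}_rep{r + 1}")
            mu = base.copy()
            if t_i > 0:
                mu = mu * np.power(2.0, config.log2_effect * direction)
            means.append(mu)
    counts = np.empty((n, len(samples)))
    for j, mu in enumerate(means):
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    mat = pd.DataFrame(counts.astype(int), index=list(gene_ids), columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "is_de": is_de,
            "log2_effect": config.log2_effect * direction,
            "direction": np.where(
                direction > 0, "up", np.where(direction < 0, "down", "none")
            ),
        }
    )
    return mat, truth


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(
    config: SimulationConfig,
    outdir: str,
    species_tree: dendropy.Tree | None = None,
) -> dict[str, str]:
    """Simulate a full dataset and write the standard input files.

    Per-species CDS FASTA, a domain table, BED-like coordinates, an
    expression matrix, and ground-truth tables. Returns the paths written.
    """
    os.makedirs(outdir, exist_ok=True)
    rng_ds = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    families = simulate_families(config, species_tree)
    genes: list[tuple[str, str]] = []
    by_species: dict[str, list[tuple[str, str]]] = {}
    fam_rows = []
    for fam in families:
        for g, seq in fam.sequences.items():
            sp = fam.species[g]
            genes.append((g, sp))
            by_species.setdefault(sp, []).append((g, seq))
            fam_rows.append({"family_id": fam.family_id, "gene_id": g, "species": sp})
    paths = {}
    for sp, recs in sorted(by_species.items()):
        path = os.path.join(outdir, f"{sp}.cds.fasta")
        with open(path, "w") as fh:
            for g, seq in recs:
                fh.write(f">{g}\n{seq}\n")
        paths[f"fasta_{sp}"] = path
    domains = assign_architectures(genes, rng_ds)
    paths["domains"] = os.path.join(outdir, "domains.tsv")
    domains.to_csv(paths["domains"], sep="\t", index=False)
    coords, hotspots = place_on_chromosomes(genes, config, rng_ds)
    paths["coordinates"] = os.path.join(outdir, "coordinates.tsv")
    coords.to_csv(paths["coordinates"], sep="\t", index=False)
    counts, truth = simulate_expression([g for g, _ in genes], config, rng_ds)
    paths["expression"] = os.path.join(outdir, "expression.tsv")
    counts.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    paths["truth_families"] = os.path.join(outdir, "truth_families.tsv")
    pd.DataFrame(fam_rows).to_csv(paths["truth_families"], sep="\t", index=False)
    paths["truth_de"] = os.path.join(outdir, "truth_de.tsv")
    truth.to_csv(paths["truth_de"], sep="\t", index=False)
    paths["truth_hotspots"] = os.path.join(outdir, "truth_hotspots.tsv")
    pd.DataFrame(hotspots, columns=["chrom_index", "bin"]).to_csv(
        paths["truth_hotspots"], sep="\t", index=False
    )
    return paths


def _check_translation(family: SimulatedFamily) -> None:
    for g, seq in family.sequences.items():
        translate(seq)
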