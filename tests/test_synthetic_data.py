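"""Ground-truth guarantees of the multi-species gene-family generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rgene_evoscan import evo_rates, synthetic_data as sd
from rgene_evoscan._codons import translate


def test_zero_branch_lengths_give_identical_sequences():
    tree = sd.fragaria_species_tree(terminal_length=0.0, internal_length=0.0)
    seqs = sd.simulate_alignment(tree, 60, 2.0, 0.2, np.random.default_rng(0))
    assert len(set(seqs.values())) == 1


def test_omega_zero_forbids_nonsynonymous_change():
    tree = sd.fragaria_species_tree(terminal_length=0.2, internal_length=0.1)
    seqs = sd.simulate_alignment(tree, 120, 2.0, 0.0, np.random.default_rng(1))
    proteins = {translate(s) for s in seqs.values()}
    assert len(proteins) == 1
    rows = list(seqs.values())
    pair = evo_rates.ng86_pair(rows[0], rows[1])
    assert pair.ka == 0.0


@pytest.mark.parametrize("seed", [0, 7, 23])
def test_simulated_families_are_reproducible_and_translation_safe(seed):
    cfg = sd.SimulationConfig(seed=seed, n_families=3)
    fams1 = sd.simulate_families(cfg)
    fams2 = sd.simulate_families(cfg)
    assert [f.sequences for f in fams1] == [f.sequences for f in fams2]
    for fam in fams1:
        for seq in fam.sequences.values():
            translate(seq)  # raises on internal stops


def test_pre_speciation_duplicates_contain_one_ortholog_per_species():
    cfg = sd.SimulationConfig(seed=5, n_pre_duplications=2, n_post_duplications=0)
    fam = sd.simulate_family(cfg)
    n_species = 6
    # three duplicate lineages, each a full species-tree copy
    assert len(fam.sequences) == 3 * n_species
    copies = {}
    for gene, sp in fam.species.items():
        copy_id = gene.split("|")[1].split("_")[0]
        copies.setdefault(copy_id, []).append(sp)
    assert len(copies) == 3
    for members in copies.values():
        assert sorted(members) == sorted(set(members))
        assert len(members) == n_species


def test_post_speciation_duplication_is_single_species():
    cfg = sd.SimulationConfig(seed=9, n_pre_duplications=0, n_post_duplications=2)
    fam = sd.simulate_family(cfg)
    post = [d for d in fam.duplications if d["timing"] == "post"]
    assert len(post) == 2
    assert all(len(d["species"]) == 1 for d in post)


def test_saturation_cap_rejects_deep_trees():
    cfg = sd.SimulationConfig(seed=0, stem_length=5.0, saturation_cap=3.0)
    with pytest.raises(ValueError, match="saturation"):
        sd.simulate_family(cfg)


class TestArchitectures:
    def test_point_mass_frequencies(self, rng):
        table = sd.assign_architectures(
            [(f"g{i}", "sp") for i in range(20)], rng, frequencies={"TNL'": 1.0}
        )
        assert set(table["architecture_class"]) == {"TNL'"}
        assert list(table[table["gene_id"] == "g0"]["domain"]) == [
            "TIR", "NB-ARC", "LRR",
        ]

    def test_zero_genes_gives_empty_table(self, rng):
        table = sd.assign_architectures([], rng)
        assert table.empty

    def test_positions_increase_without_overlap(self, rng):
        table = sd.assign_architectures([(f"g{i}", "sp") for i in range(50)], rng)
        for _, sub in table.groupby("gene_id"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts <= ends).all()
            assert (starts[1:] > ends[:-1]).all()

    def test_default_frequencies_within_binomial_bounds(self):
        rng = np.random.default_rng(1234)
        n = 1000
        table = sd.assign_architectures([(f"g{i}", "sp") for i in range(n)], rng)
        freqs = sd.default_architecture_frequencies()
        counts = (
            table.drop_duplicates("gene_id")["architecture_class"]
            .value_counts()
            .to_dict()
        )
        for cls, f in freqs.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], n, f)
            assert lo <= counts.get(cls, 0) <= hi


class TestPlacement:
    def test_no_enrichment_is_uniform(self):
        rng = np.random.default_rng(7)
        cfg = sd.SimulationConfig(
            seed=7, n_chromosomes=2, hotspot_enrichment=1.0, n_hotspot_bins=1
        )
        genes = [(f"g{i}", "sp") for i in range(2000)]
        coords, _ = sd.place_on_chromosomes(genes, cfg, rng)
        bins = coords["start"] // cfg.bin_size + np.where(
            coords["chrom"] == "chr2", 25, 0
        )
        observed = np.bincount(bins, minlength=50)
        _, p = stats.chisquare(observed)
        assert p > 0.01

    def test_planted_bin_is_per_chromosome_maximum_in_every_species(self):
        rng = np.random.default_rng(11)
        cfg = sd.SimulationConfig(
            seed=11, n_chromosomes=3, hotspot_enrichment=10.0, n_hotspot_bins=1
        )
        genes = [(f"g{i}_{sp}", sp) for i in range(80) for sp in sd.SPECIES]
        coords, planted = sd.place_on_chromosomes(genes, cfg, rng)
        (chrom, hot_bin) = planted[0]
        for sp in sd.SPECIES:
            sub = coords[(coords["species"] == sp) & (coords["chrom"] == f"chr{chrom}")]
            counts = (sub["start"] // cfg.bin_size).value_counts()
            assert counts.idxmax() == hot_bin

    def test_no_genes_empty_table(self, rng):
        cfg = sd.SimulationConfig(seed=0)
        coords, _ = sd.place_on_chromosomes([], cfg, rng)
        assert coords.empty

    def test_chromosome_must_exceed_bin(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(seed=0, chromosome_length=500_000)


class TestExpression:
    def test_flat_gene_never_flagged(self):
        from rgene_evoscan import expression as ex

        counts = pd.DataFrame(
            {"a1": [50, 9], "a2": [50, 11], "b1": [50, 200], "b2": [50, 180]},
            index=["flat", "de"],
        )
        lfc = ex.log_fold_change(counts, ["a1", "a2"], ["b1", "b2"])
        assert lfc["flat"] == 0.0
        degs = ex.screen_degs(lfc, pd.Series([0.001, 0.001], index=counts.index))
        assert "flat" not in {d.gene_id for d in degs}

    def test_truth_labels_match_effect(self, rng):
        cfg = sd.SimulationConfig(seed=3, de_fraction=0.3)
        counts, truth = sd.simulate_expression(
            [f"g{i}" for i in range(200)], cfg, rng
        )
        assert counts.shape == (200, 2 * cfg.n_samples_per_condition)
        assert set(truth[truth["is_de"]]["direction"]) <= {"up", "down"}
        assert (truth[~truth["is_de"]]["log2_effect"] == 0).all()

    def test_needs_one_sample_per_condition(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(seed=0, n_samples_per_condition=0)


def test_write_dataset_round_trip(tmp_path):
    cfg = sd.SimulationConfig(seed=2, n_families=2, n_codons=60)
    paths = sd.write_dataset(cfg, str(tmp_path))
    domains = pd.read_csv(paths["domains"], sep="\t")
    coords = pd.read_csv(paths["coordinates"], sep="\t")
    members = pd.read_csv(paths["truth_families"], sep="\t")
    assert set(domains["gene_id"]) == set(members["gene_id"])
    assert set(coords["gene_id"]) == set(members["gene_id"])
    expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    assert list(expr.index) == list(members["gene_id"])
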