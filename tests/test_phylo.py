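"""Distances, neighbor joining, duplication-clade typing, branch contrasts."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from rgene_evoscan import phylo, synthetic_data as sd

from _oracles import tree_path_distances


class TestJcDistance:
    def test_identical_rows_zero(self):
        d = phylo.jc_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert d.loc["a", "b"] == 0.0

    def test_closed_form_at_p_03(self):
        # 3 mismatches in 10 sites -> p = 0.3
        d = phylo.jc_distance_matrix({"a": "AAAAAAAAAA", "b": "CCCAAAAAAA"})
        assert d.loc["a", "b"] == pytest.approx(-0.75 * np.log(0.6), abs=1e-10)

    def test_saturated_pair_marked_invalid(self):
        d = phylo.jc_distance_matrix({"a": "AAAA", "b": "CCCC"})
        assert np.isnan(d.loc["a", "b"])

    def test_all_gap_overlap_invalid(self):
        d = phylo.jc_distance_matrix({"a": "AA--", "b": "--CC"})
        assert np.isnan(d.loc["a", "b"])


def random_additive_tree(n_taxa, seed):
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n_taxa, rng=__import__("random").Random(seed),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.1, 2.0))
    return tree


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (8, 3)])
    def test_recovers_additive_matrices_exactly(self, n_taxa, seed):
        true_tree = random_additive_tree(n_taxa, seed)
        truth = tree_path_distances(true_tree)
        labels = sorted({x for pair in truth for x in pair})
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for (a, b), dist in (
            (tuple(sorted(k)), v) for k, v in truth.items()
        ):
            mat.loc[a, b] = mat.loc[b, a] = dist
        nj = phylo.neighbor_joining(mat)
        recovered = tree_path_distances(nj)
        for pair, dist in truth.items():
            assert recovered[pair] == pytest.approx(dist, abs=1e-9)

    def test_three_taxa_closed_form(self):
        mat = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        nj = phylo.neighbor_joining(mat)
        d = tree_path_distances(nj)
        assert d[frozenset(("a", "b"))] == pytest.approx(3.0)
        assert d[frozenset(("a", "c"))] == pytest.approx(4.0)
        assert d[frozenset(("b", "c"))] == pytest.approx(5.0)

    def test_taxon_order_invariance(self):
        true_tree = random_additive_tree(6, 7)
        truth = tree_path_distances(true_tree)
        labels = sorted({x for pair in truth for x in pair})
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for k, v in truth.items():
            a, b = sorted(k)
            mat.loc[a, b] = mat.loc[b, a] = v
        perm = labels[::-1]
        d1 = tree_path_distances(phylo.neighbor_joining(mat))
        d2 = tree_path_distances(
            phylo.neighbor_joining(mat.loc[perm, perm])
        )
        assert all(d1[k] == pytest.approx(d2[k], abs=1e-9) for k in d1)

    def test_invalid_entries_rejected(self):
        mat = pd.DataFrame(
            [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
            index=list("abc"), columns=list("abc"),
        )
        with pytest.raises(ValueError):
            phylo.neighbor_joining(mat)


def build_tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


class TestCladeLabels:
    def test_root_duplication_across_species_is_lineage_specific(self):
        t = build_tree("((A|1:1,B|1:1):1,(A|2:1,B|2:1):1):0;")
        t.is_rooted = True
        labels = phylo.label_duplication_clades(t)
        root_row = labels[labels["n_genes"] == 4].iloc[0]
        assert root_row["type"] == "lineage-specific"
        assert root_row["maximal_clade"]

    def test_single_species_clade_is_species_specific(self):
        t = build_tree("(A|1:1,(A|2:1,A|3:1):1):0;")
        t.is_rooted = True
        labels = phylo.label_duplication_clades(t)
        assert set(labels["type"]) == {"species-specific"}

    def test_speciation_only_tree_has_no_duplications(self):
        t = build_tree("((A|1:1,B|1:1):1,(C|1:1,D|1:1):1):0;")
        t.is_rooted = True
        labels = phylo.label_duplication_clades(t)
        assert set(labels["type"]) == {"speciation"}

    def test_every_internal_node_gets_exactly_one_label(self):
        t = build_tree("((A|1:1,A|2:1):1,(B|1:1,(B|2:1,C|1:1):1):1):0;")
        t.is_rooted = True
        labels = phylo.label_duplication_clades(t)
        n_internal = sum(1 for n in t.preorder_node_iter() if not n.is_leaf())
        assert len(labels) == n_internal
        assert labels["type"].isin(
            ["speciation", "species-specific", "lineage-specific"]
        ).all()

    def test_child_order_invariance(self):
        t1 = build_tree("((A|1:1,B|1:1):1,(A|2:1,B|2:1):1):0;")
        t2 = build_tree("((B|2:1,A|2:1):1,(B|1:1,A|1:1):1):0;")
        for t in (t1, t2):
            t.is_rooted = True
        s1 = phylo.clade_type_summary(phylo.label_duplication_clades(t1))
        s2 = phylo.clade_type_summary(phylo.label_duplication_clades(t2))
        assert s1 == s2

    def test_missing_species_label_is_error(self):
        t = build_tree("(x:1,(A|2:1,A|3:1):1):0;")
        t.is_rooted = True
        with pytest.raises(ValueError):
            phylo.label_duplication_clades(t)

    def test_simulated_duplication_timing_recovered(self):
        """NJ trees from simulated families recover the planted duplication
        types (pre-speciation -> lineage-specific at the root region;
        post-speciation -> a species-specific clade)."""
        correct = 0
        total = 0
        for seed in range(20):
            cfg = sd.SimulationConfig(
                seed=seed, n_pre_duplications=1, n_post_duplications=1,
                stem_length=0.3,
            )
            fam = sd.simulate_family(cfg)
            tree = phylo.nj_tree(fam.sequences)
            labels = phylo.label_duplication_clades(phylo.midpoint_root(tree))
            for dup in fam.duplications:
                total += 1
                if dup["timing"] == "pre":
                    match = labels[
                        (labels["type"] == "lineage-specific")
                        & (labels["n_species"] == 6)
                    ]
                else:
                    match = labels[labels["type"] == "species-specific"]
                if len(match):
                    correct += 1
        assert correct >= 0.95 * total


class TestBranchContrast:
    def test_equal_branches_give_t_zero(self):
        t = build_tree("((a:1,b:1):1,(c:1,d:1):1):0;")
        out = phylo.branch_length_contrast(
            [t], {"a": "I", "b": "I", "c": "II", "d": "II"}
        )
        assert out.iloc[0]["t"] == pytest.approx(0.0)

    def test_planted_rate_difference_detected(self):
        rng = np.random.default_rng(5)
        trees = []
        group = {}
        for k in range(12):
            la, lb, ia = rng.normal(0.04, 0.005, 3).clip(0.001)
            lc, ld, ic = rng.normal(0.08, 0.005, 3).clip(0.001)
            trees.append(
                build_tree(
                    f"((a{k}:{la},b{k}:{lb}):{ia},(c{k}:{lc},d{k}:{ld}):{ic}):0;"
                )
            )
            group.update(
                {f"a{k}": "I", f"b{k}": "I", f"c{k}": "II", f"d{k}": "II"}
            )
        out = phylo.branch_length_contrast(trees, group)
        row = out.iloc[0]
        assert row["p"] < 0.01
        assert abs(row["mean_a"] - 0.04) < 0.01
        assert abs(row["mean_b"] - 0.08) < 0.01

    def test_empty_tree_set_is_error(self):
        with pytest.raises(ValueError):
            phylo.branch_length_contrast([], {})
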