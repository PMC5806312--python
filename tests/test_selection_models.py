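"""GY94 generator, pruning likelihood and the M0 / M7-vs-M8 machinery."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from rgene_evoscan import synthetic_data as sd
from rgene_evoscan import selection_models as sm
from rgene_evoscan._codons import CODON_INDEX, N_SENSE


class TestGenerator:
    def test_omega_zero_kills_nonsynonymous_rates(self):
        q = sm.gy94_generator(2.0, 0.0, scale="none")
        from rgene_evoscan.selection_models import _SINGLE, _SYN

        nonsyn = _SINGLE & ~_SYN
        assert np.all(q[nonsyn] == 0.0)

    def test_rows_sum_to_zero(self):
        q = sm.gy94_generator(3.0, 0.7)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_multi_position_changes_forbidden(self):
        from rgene_evoscan.selection_models import _SINGLE

        q = sm.gy94_generator(2.0, 1.0, scale="none")
        off = ~np.eye(N_SENSE, dtype=bool)
        assert np.all(q[off & ~_SINGLE] == 0.0)

    def test_detailed_balance(self):
        pi = sm.uniform_codon_frequencies()
        q = sm.gy94_generator(2.5, 0.4, pi=pi)
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_synonymous_scaling_is_omega_independent(self):
        # the synonymous flow does not involve omega, so Ks-scale
        # generators for different omega share the same synonymous part
        from rgene_evoscan.selection_models import _SYN

        q1 = sm.gy94_generator(2.0, 0.1, scale="synonymous")
        q2 = sm.gy94_generator(2.0, 3.0, scale="synonymous")
        assert np.allclose(q1[_SYN], q2[_SYN])

    def test_codon_scaling_normalizes_rate(self):
        pi = sm.uniform_codon_frequencies()
        q = sm.gy94_generator(2.0, 0.5, pi=pi, scale="codon")
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)


class TestChiSquareThresholds:
    def test_critical_values_to_three_decimals(self):
        assert sm.chi2_critical(0.05) == pytest.approx(5.991, abs=5e-4)
        assert sm.chi2_critical(0.01) == pytest.approx(9.210, abs=5e-4)

    @pytest.mark.parametrize(
        "stat,tier", [(6.5, "*"), (12.0, "**"), (3.0, "ns"), (9.210, "*"),
                      (5.991, "ns")],
    )
    def test_tier_assignment(self, stat, tier):
        assert sm.tier_from_two_delta_ln(stat) == tier


class TestLikelihood:
    def test_single_sequence_is_stationary_log_probability(self):
        tree = dendropy.Tree.get(data="(A:1.0);", schema="newick")
        seq = "ATGAAATTT"
        ll = sm.log_likelihood({"A": seq}, tree, kappa=2.0, omegas=[0.5])
        pi = sm.uniform_codon_frequencies()
        expected = sum(
            np.log(pi[CODON_INDEX[seq[i : i + 3]]]) for i in range(0, 9, 3)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_matches_matrix_exponential(self, rng):
        a, b = sd.simulate_codon_pair(40, 0.4, 0.3, rng=rng)
        tree = dendropy.Tree.get(data="(A:0.15,B:0.25);", schema="newick")
        ll = sm.log_likelihood({"A": a, "B": b}, tree, kappa=2.0, omegas=[0.3])
        pi = sm.uniform_codon_frequencies()
        p = expm(sm.gy94_generator(2.0, 0.3) * 0.4)
        oracle = sum(
            np.log(
                pi[CODON_INDEX[a[i : i + 3]]]
                * p[CODON_INDEX[a[i : i + 3]], CODON_INDEX[b[i : i + 3]]]
            )
            for i in range(0, len(a), 3)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_duplicated_columns_are_additive(self, quartet_tree, rng):
        seqs = sd.simulate_alignment(quartet_tree, 10, 2.0, 0.5, rng)
        ll1 = sm.log_likelihood(seqs, quartet_tree, kappa=2.0, omegas=[0.5])
        doubled = {k: v + v for k, v in seqs.items()}
        ll2 = sm.log_likelihood(doubled, quartet_tree, kappa=2.0, omegas=[0.5])
        assert ll2 == pytest.approx(2 * ll1, abs=1e-8)

    def test_leaf_reordering_invariance(self, quartet_tree, rng):
        seqs = sd.simulate_alignment(quartet_tree, 20, 2.0, 0.5, rng)
        reordered = {k: seqs[k] for k in sorted(seqs, reverse=True)}
        ll1 = sm.log_likelihood(seqs, quartet_tree, kappa=2.0, omegas=[0.5])
        ll2 = sm.log_likelihood(reordered, quartet_tree, kappa=2.0, omegas=[0.5])
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_rerooting_invariance(self, quartet_tree, rng):
        # same unrooted tree, rooted along A's terminal edge instead
        seqs = sd.simulate_alignment(quartet_tree, 20, 2.0, 0.5, rng)
        ll1 = sm.log_likelihood(seqs, quartet_tree, kappa=2.0, omegas=[0.5])
        rerooted = dendropy.Tree.get(
            data="(A:0.05,(B:0.1,(C:0.1,D:0.1):0.1):0.05);",
            schema="newick",
        )
        ll2 = sm.log_likelihood(seqs, rerooted, kappa=2.0, omegas=[0.5])
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_gap_codons_are_missing_data(self, quartet_tree, rng):
        seqs = sd.simulate_alignment(quartet_tree, 20, 2.0, 0.5, rng)
        gapped = dict(seqs)
        name = sorted(gapped)[0]
        gapped[name] = "---" + gapped[name][3:]
        ll = sm.log_likelihood(gapped, quartet_tree, kappa=2.0, omegas=[0.5])
        assert np.isfinite(ll)

    def test_empty_alignment_is_error(self, quartet_tree):
        with pytest.raises(ValueError):
            sm.log_likelihood({}, quartet_tree, kappa=2.0)


class TestBetaClasses:
    def test_equal_probability_medians(self):
        om = sm.beta_class_omegas(2.0, 2.0, 10)
        assert len(om) == 10
        assert np.all(np.diff(om) > 0)
        assert np.all((om > 0) & (om < 1))

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError):
            sm.beta_class_omegas(1.0, 1.0, 2)

    def test_m8_adds_positive_class(self):
        omegas, weights = sm.m8_classes(0.5, 1.5, 0.2, 2.5, 10)
        assert omegas[-1] == 2.5
        assert weights[-1] == pytest.approx(0.2)
        assert weights.sum() == pytest.approx(1.0)


class TestFits:
    def test_m0_needs_three_members(self, rng):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        a, b = sd.simulate_codon_pair(30, 0.2, 0.5, rng=rng)
        with pytest.raises(ValueError, match="at least 3"):
            sm.fit_m0({"A": a, "B": b}, tree)

    def test_identical_sequences_flagged_unidentifiable(self, quartet_tree):
        seqs = {n: "ATGAAATTTGGG" for n in "ABCD"}
        res = sm.fit_m0(seqs, quartet_tree)
        assert not res.converged
        assert np.isnan(res.params["omega"])

    def test_m0_beats_omega_grid(self, quartet_tree, rng):
        seqs = sd.simulate_alignment(quartet_tree, 120, 2.0, 0.3, rng)
        res = sm.fit_m0(seqs, quartet_tree)
        assert res.converged
        for omega in (0.05, 0.1, 0.5, 1.0, 2.0):
            ll = sm.log_likelihood(
                seqs, quartet_tree,
                kappa=res.params["kappa"], omegas=[omega],
                pi=sm.f3x4_frequencies(
                    sm.encode_codon_alignment(seqs)[1]
                ),
                branch_scale=res.params["branch_scale"],
            )
            assert res.log_likelihood >= ll - 1e-6

    def test_m8_never_below_m7(self, quartet_tree, rng):
        seqs = sd.simulate_alignment(quartet_tree, 60, 2.0, 0.2, rng)
        result = sm.lrt_m7_m8(seqs, quartet_tree)
        assert result.lnl_m8 >= result.lnl_m7 - 1e-4
        assert result.two_delta_ln >= 0.0

    def test_strong_positive_selection_detected(self):
        tree = sd.fragaria_species_tree(
            terminal_length=0.15, internal_length=0.10
        )
        rng = np.random.default_rng(77)
        cats = sm.beta_class_omegas(0.5, 1.5, 10)
        site_omegas = cats[rng.integers(0, 10, 300)]
        site_omegas = np.where(rng.random(300) < 0.2, 3.0, site_omegas)
        seqs = sd.simulate_alignment(tree, 300, 2.0, site_omegas, rng)
        from rgene_evoscan import phylo

        result = sm.lrt_m7_m8(seqs, phylo.nj_tree(seqs))
        assert result.tier == "**"
        assert len(result.positive_sites) > 0


def test_f3x4_frequencies_sum_to_one(quartet_tree, rng):
    seqs = sd.simulate_alignment(quartet_tree, 50, 2.0, 0.5, rng)
    _, mat = sm.encode_codon_alignment(seqs)
    pi = sm.f3x4_frequencies(mat)
    assert pi.sum() == pytest.approx(1.0)
    assert np.all(pi > 0)
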