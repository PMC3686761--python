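"""Codon frequencies, rate matrix, transition matrices, pruning likelihood."""

from __future__ import annotations

import numpy as np
import pytest

from psgscan.branchsite import (
    BranchSiteParams,
    CodonFrequencies,
    brute_force_loglik,
    build_rate_matrix,
    estimate_codon_frequencies_f3x4,
    model_a_loglik,
    substitution_rate,
    transition_matrix,
)
from psgscan.codon_align import CodonAlignment
from psgscan.codons import CODON_INDEX, N_CODONS, SENSE_CODONS, SINGLE_DIFF_SYNONYMOUS
from psgscan.simulate import simulate_codon_alignment
from psgscan.trees import LabeledTree


def random_pi(rng: np.random.Generator) -> np.ndarray:
    pi = rng.dirichlet(np.ones(N_CODONS))
    return pi / pi.sum()


class TestF3x4:
    def test_uniform_composition_gives_one_over_61(self):
        # AAA CCC GGG TTT: every base equally frequent at every position
        caln = CodonAlignment({"sp": "AAACCCGGGTTT"})
        freqs = estimate_codon_frequencies_f3x4(caln)
        assert np.allclose(freqs.pi, 1.0 / N_CODONS)

    def test_single_sequence_hand_count(self):
        caln = CodonAlignment({"sp": "ATGAAA"})
        freqs = estimate_codon_frequencies_f3x4(caln)
        # direct product oracle from the two codons ATG and AAA
        f = [{"A": 1.0}, {"T": 0.5, "A": 0.5}, {"G": 0.5, "A": 0.5}]
        raw = {
            c: f[0].get(c[0], 0) * f[1].get(c[1], 0) * f[2].get(c[2], 0)
            for c in SENSE_CODONS
        }
        total = sum(raw.values())
        for codon, value in raw.items():
            assert freqs.pi[CODON_INDEX[codon]] == pytest.approx(value / total)
        assert set(freqs.zero_codons) == {c for c, v in raw.items() if v == 0}

    def test_all_gap_column_contributes_nothing(self):
        a = CodonAlignment({"x": "ATGAAA", "y": "TGGCAT"})
        b = CodonAlignment({"x": "ATGAAA---", "y": "TGGCAT---"})
        assert np.allclose(
            estimate_codon_frequencies_f3x4(a).pi,
            estimate_codon_frequencies_f3x4(b).pi,
        )


class TestRateMatrix:
    def test_rows_sum_to_zero_and_multistep_changes_forbidden(self, rng):
        Q = build_rate_matrix(2.5, 0.3, random_pi(rng))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        for i, ci in enumerate(SENSE_CODONS[:10]):
            for j, cj in enumerate(SENSE_CODONS):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert Q[i, j] == 0.0

    def test_detailed_balance(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(3.0, 0.7, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_omega_zero_kills_nonsynonymous_rates(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(2.0, 0.0, pi)
        from psgscan.codons import SINGLE_DIFF_PAIRS

        i, j = SINGLE_DIFF_PAIRS[:, 0], SINGLE_DIFF_PAIRS[:, 1]
        nonsyn = ~SINGLE_DIFF_SYNONYMOUS
        assert np.all(Q[i[nonsyn], j[nonsyn]] == 0.0)
        assert np.any(Q[i[~nonsyn], j[~nonsyn]] > 0.0)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, rng):
        Q = build_rate_matrix(2.0, 0.5, random_pi(rng))
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(N_CODONS))

    def test_rows_sum_to_one_and_entries_nonnegative(self, rng):
        for _ in range(3):
            pi = random_pi(rng)
            kappa = float(rng.uniform(0.5, 5))
            omega = float(rng.uniform(0, 3))
            t = float(rng.uniform(0, 2))
            Q = build_rate_matrix(kappa, omega, pi)
            P = transition_matrix(Q / substitution_rate(Q, pi), t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12

    def test_semigroup_property(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(1.8, 0.4, pi)
        Q = Q / substitution_rate(Q, pi)
        t1, t2 = 0.23, 0.71
        P12 = transition_matrix(Q, t1 + t2)
        assert np.allclose(
            P12, transition_matrix(Q, t1) @ transition_matrix(Q, t2), atol=1e-10
        )


PARAMS = BranchSiteParams(kappa=2.2, omega0=0.15, omega2=3.5, p0=0.6, p1=0.25)


class TestModelALoglik:
    def test_zero_branch_lengths_reduce_to_log_pi(self):
        tree = LabeledTree.from_newick("(A#1:0,B:0);")
        caln = CodonAlignment({"A": "ATGAAATGG", "B": "ATGAAATGG"})
        pi = CodonFrequencies.uniform()
        ll = model_a_loglik(caln, tree, PARAMS, pi)
        expected = sum(np.log(pi.pi[CODON_INDEX[c]]) for c in ["ATG", "AAA", "TGG"])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_bruteforce_enumeration_on_small_trees(self):
        # the full randomized suite runs in the acceptance tests; spot-check here
        pi = CodonFrequencies.uniform()
        for seed, newick in [
            (1, "(A#1:0.1,B:0.3,C:0.2);"),
            (2, "((A:0.15,B:0.2)ab#1:0.1,C:0.25,D:0.1);"),
        ]:
            tree = LabeledTree.from_newick(newick)
            caln, _ = simulate_codon_alignment(tree, PARAMS, pi, 4, seed=seed)
            assert model_a_loglik(caln, tree, PARAMS, pi) == pytest.approx(
                brute_force_loglik(caln, tree, PARAMS, pi), abs=1e-8
            )

    def test_omega2_equal_one_matches_null_parameterization(self):
        pi = CodonFrequencies.uniform()
        tree = LabeledTree.from_newick("(A#1:0.1,B:0.3,C:0.2);")
        caln, _ = simulate_codon_alignment(tree, PARAMS, pi, 30, seed=4)
        at_one = BranchSiteParams(kappa=2.2, omega0=0.15, omega2=1.0, p0=0.6, p1=0.25)
        assert model_a_loglik(caln, tree, at_one, pi) == pytest.approx(
            brute_force_loglik(caln, tree, at_one, pi), abs=1e-8
        )

    def test_loglik_invariant_to_root_placement(self):
        # same unrooted tree, two rootings; foreground edge preserved
        pi = CodonFrequencies.uniform()
        t1 = LabeledTree.from_newick("((A#1:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
        t2 = LabeledTree.from_newick("(((A#1:0.1,B:0.2):0.12,C:0.3):0.04,D:0.06);")
        caln, _ = simulate_codon_alignment(t1, PARAMS, pi, 40, seed=8)
        ll1 = model_a_loglik(caln, t1, PARAMS, pi)
        ll2 = model_a_loglik(caln, t2, PARAMS, pi)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_species_mismatch_raises(self):
        pi = CodonFrequencies.uniform()
        tree = LabeledTree.from_newick("(A#1:0.1,B:0.3,Z:0.2);")
        caln = CodonAlignment({"A": "ATG", "B": "ATG", "C": "ATG"})
        with pytest.raises(ValueError, match="Z"):
            model_a_loglik(caln, tree, PARAMS, pi)

    def test_gap_and_ambiguous_codons_enter_as_missing_data(self):
        # marginalizing B's codon over all states equals an explicit sum
        pi = CodonFrequencies.uniform()
        tree = LabeledTree.from_newick("(A#1:0.1,B:0.3,C:0.2);")
        base = {"A": "ATG", "C": "TGG"}
        ll_gap = model_a_loglik(
            CodonAlignment({**base, "B": "---"}), tree, PARAMS, pi
        )
        liks = [
            np.exp(
                model_a_loglik(CodonAlignment({**base, "B": c}), tree, PARAMS, pi)
            )
            for c in SENSE_CODONS
        ]
        assert ll_gap == pytest.approx(np.log(sum(liks)), abs=1e-8)


def test_branch_site_params_class_proportions_sum_to_one():
    props = PARAMS.proportions
    assert props.sum() == pytest.approx(1.0)
    # class map: {0: (w0, w0), 1: (1, 1), 2a: (w0, w2), 2b: (1, w2)}
    assert PARAMS.background_omegas == (0.15, 1.0, 0.15, 1.0)
    assert PARAMS.foreground_omegas == (0.15, 1.0, 3.5, 3.5)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(kappa=-1, omega0=0.5, omega2=2, p0=0.5, p1=0.3),
        dict(kappa=2, omega0=1.5, omega2=2, p0=0.5, p1=0.3),
        dict(kappa=2, omega0=0.5, omega2=0.5, p0=0.5, p1=0.3),
        dict(kappa=2, omega0=0.5, omega2=2, p0=0.8, p1=0.3),
        dict(kappa=2, omega0=0.5, omega2=2, p0=0.0, p1=0.0),
    ],
)
def test_invalid_branch_site_params_rejected(kwargs):
    with pytest.raises(ValueError):
        BranchSiteParams(**kwargs)
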