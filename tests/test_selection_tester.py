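"""Codon alignment prep, Nc, site-model likelihoods and LRTs."""

import numpy as np
import pytest

from delscape import selection_tester as st
from delscape import simdata
from delscape._tree import SimpleTree
from delscape.codon_model import (CODON_INDEX, GENETIC_CODE, SENSE_CODONS,
                                  uniform_frequencies)

from oracles import two_taxon_loglike


def toy_alignment(seqs):
    ids = list(seqs)
    codons = np.array([[CODON_INDEX[s[i:i + 3]]
                        for i in range(0, len(s), 3)]
                       for s in seqs.values()])
    return st.CodonAlignment(ids, codons)


class TestPrepareCodonAlignment:
    def test_gap_free_alignment_unchanged(self):
        msa = {"a": "ATGAAACCC", "b": "ATGAAGCCC", "c": "ATGAAACCG"}
        aln = st.prepare_codon_alignment(msa)
        assert aln.ids == ["a", "b", "c"]
        assert aln.n_codons == 3
        assert not aln.excluded_sequences and not aln.excluded_columns

    def test_long_indel_drops_the_sequence_not_the_columns(self):
        clean = "ATGAAACCCGGGTTTAAACAT"          # 7 codons
        gappy = "ATG" + "-" * 18                 # 18-nt indel (> 5 aa)
        msa = {"a": clean, "b": clean, "c": clean, "d": gappy}
        aln = st.prepare_codon_alignment(msa)
        assert aln.excluded_sequences == ["d"]
        assert aln.n_codons == 7

    def test_short_gap_drops_only_the_codon_column(self):
        msa = {"a": "ATGAAACCC", "b": "ATG---CCC", "c": "ATGAAACCG"}
        aln = st.prepare_codon_alignment(msa)
        assert aln.excluded_sequences == []
        assert aln.excluded_columns == [1]
        assert aln.n_codons == 2

    def test_stop_containing_columns_excluded(self):
        msa = {"a": "ATGTAACCC", "b": "ATGAAACCC", "c": "ATGAAACCG"}
        aln = st.prepare_codon_alignment(msa)
        assert aln.excluded_columns == [1]

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            st.prepare_codon_alignment({"a": "ATG", "b": "ATG"})

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            st.prepare_codon_alignment({"a": "ATGA", "b": "ATGA",
                                        "c": "ATGA"})


class TestEffectiveNumberOfCodons:
    def test_uniform_synonymous_usage_reaches_sixty_one(self):
        usage = {c: 1.0 for c in SENSE_CODONS}
        assert st.effective_number_of_codons(usage) \
            == pytest.approx(61.0)

    def test_single_codon_per_amino_acid_evaluates_to_twenty(self):
        usage = {}
        seen = set()
        for c, aa in GENETIC_CODE.items():
            if aa != "*" and aa not in seen:
                usage[c] = 10.0
                seen.add(aa)
        # 2 + 9/1 + 1/1 + 5/1 + 3/1 by direct formula evaluation
        assert st.effective_number_of_codons(usage) == pytest.approx(20.0)

    def test_two_fold_homozygosity_hand_value(self):
        # every 2-fold amino acid at p=(0.7,0.3): F2 = 0.49+0.09 = 0.58;
        # all other classes uniform
        usage = {c: 1.0 for c in SENSE_CODONS}
        twofold = {}
        for c in SENSE_CODONS:
            aa = GENETIC_CODE[c]
            syn = [x for x in SENSE_CODONS if GENETIC_CODE[x] == aa]
            if len(syn) == 2:
                twofold.setdefault(aa, syn)
        for syn in twofold.values():
            usage[syn[0]], usage[syn[1]] = 0.7, 0.3
        expected = 2.0 + 9.0 / 0.58 + 1.0 / (1 / 3) + 5.0 / (1 / 4) \
            + 3.0 / (1 / 6)
        assert st.effective_number_of_codons(usage) \
            == pytest.approx(expected)

    def test_invariant_to_total_scaling(self):
        rng = np.random.default_rng(2)
        usage = {c: float(rng.integers(1, 50)) for c in SENSE_CODONS}
        a = st.effective_number_of_codons(usage)
        b = st.effective_number_of_codons(
            {c: 1000.0 * v for c, v in usage.items()})
        assert a == pytest.approx(b)

    def test_never_exceeds_sixty_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            usage = {c: float(rng.random() + 0.01) for c in SENSE_CODONS}
            assert st.effective_number_of_codons(usage) <= 61.0

    def test_per_sequence_report_shape(self):
        nwk = simdata.random_tree(4, 0.1, seed=4)
        seqs, _ = simdata.simulate_codon_alignment(nwk, 300, seed=5)
        table = st.nc_report(st.prepare_codon_alignment(seqs))
        assert len(table) == 4
        assert 20.0 <= table.attrs["mean"] <= 61.0


class TestLikelihood:
    @pytest.mark.parametrize("kappa,omega,ta,tb", [
        (2.0, 0.5, 0.1, 0.3),
        (1.0, 1.0, 0.05, 0.05),
        (5.0, 0.1, 0.4, 0.2),
    ])
    def test_two_taxon_pruning_matches_expm_oracle(self, kappa, omega,
                                                   ta, tb):
        seqs = {"a": "ATGAAACCCGGGTAT", "b": "ATGAAGCCGGGTTAT"}
        aln = toy_alignment(seqs)
        pi = uniform_frequencies()
        tree = SimpleTree.from_newick(f"(a:{ta},b:{tb});")
        pruner = st._Pruner(aln, tree)
        got = st._mixture_lnl(pruner, pi, kappa, (omega,), (1.0,), 1.0)
        want = two_taxon_loglike(seqs["a"], seqs["b"], ta, tb, kappa,
                                 omega, pi)
        assert got == pytest.approx(want, abs=1e-8)

    def test_identical_pair_one_codon_converges_to_log_pi(self):
        seqs = {"a": "ATG", "b": "ATG"}
        aln = toy_alignment(seqs)
        pi = uniform_frequencies()
        fit = st.fit_site_model(aln, "(a:0.5,b:0.5);", "M0", pi=pi)
        assert fit.lnl == pytest.approx(np.log(pi[CODON_INDEX["ATG"]]),
                                        abs=1e-3)

    def test_mixture_likelihood_reduces_to_single_class_at_unit_weight(self):
        nwk = simdata.random_tree(5, 0.1, seed=6)
        seqs, _ = simdata.simulate_codon_alignment(nwk, 50, seed=7)
        aln = st.prepare_codon_alignment(seqs)
        tree = SimpleTree.from_newick(nwk)
        pruner = st._Pruner(aln, tree)
        pi = uniform_frequencies()
        one = st._mixture_lnl(pruner, pi, 2.0, (0.3,), (1.0,), 1.0)
        two = st._mixture_lnl(pruner, pi, 2.0, (0.3, 1.0), (1.0, 0.0), 1.0)
        assert one == pytest.approx(two, abs=1e-9)


@pytest.fixture(scope="module")
def m1a_dataset():
    nwk = simdata.random_tree(12, 0.08, seed=8)
    seqs, _ = simdata.simulate_codon_alignment(
        nwk, 300, model="M1a", kappa=2.0, omegas=(0.1, 1.0),
        proportions=(0.85, 0.15), seed=9)
    aln = st.prepare_codon_alignment(seqs)
    m0 = st.fit_site_model(aln, nwk, "M0")
    m1 = st.fit_site_model(aln, nwk, "M1a", warm_start=m0)
    m2 = st.fit_site_model(aln, nwk, "M2a", warm_start=m1)
    return m0, m1, m2


class TestModelFits:
    def test_nesting_never_decreases_likelihood(self, m1a_dataset):
        m0, m1, m2 = m1a_dataset
        assert m1.lnl >= m0.lnl - 1e-4
        assert m2.lnl >= m1.lnl - 1e-4

    def test_m1a_parameter_recovery_and_power_at_twenty_taxa(self):
        nwk = simdata.random_tree(20, 0.08, seed=2)
        seqs, _ = simdata.simulate_codon_alignment(
            nwk, 500, model="M1a", kappa=2.0, omegas=(0.05, 1.0),
            proportions=(0.9, 0.1), seed=12)
        aln = st.prepare_codon_alignment(seqs)
        m0 = st.fit_site_model(aln, nwk, "M0")
        m1 = st.fit_site_model(aln, nwk, "M1a", warm_start=m0)
        assert m1.proportions[0] == pytest.approx(0.9, abs=0.1)
        assert m1.omegas[0] == pytest.approx(0.05, abs=0.05)
        # the two-class structure is decisively preferred at this scale
        assert st.lrt(m0, m1).p_value < 0.001

    def test_omega_class_structure_per_model(self, m1a_dataset):
        m0, m1, m2 = m1a_dataset
        assert len(m0.omegas) == 1
        assert m1.omegas[1] == 1.0 and 0.0 <= m1.omegas[0] < 1.0
        assert m2.omegas[2] > 1.0
        for fit in (m0, m1, m2):
            assert sum(fit.proportions) == pytest.approx(1.0)

    def test_unknown_model_rejected(self, m1a_dataset):
        aln = toy_alignment({"a": "ATG", "b": "ATG", "c": "ATG"})
        with pytest.raises(ValueError):
            st.fit_site_model(aln, "(a:0.1,(b:0.1,c:0.1):0.1);", "M8")

    def test_mismatched_tree_rejected(self):
        aln = toy_alignment({"a": "ATG", "b": "ATG", "c": "ATG"})
        with pytest.raises(ValueError):
            st.fit_site_model(aln, "(a:0.1,(b:0.1,x:0.1):0.1);", "M0")


class TestLRT:
    def test_identical_fits_give_zero_statistic_and_p_one(self, m1a_dataset):
        m0, _, _ = m1a_dataset
        res = st.lrt(m0, st.CodonModelFit(
            "M1a", m0.kappa, (m0.omegas[0], 1.0), (1.0, 0.0),
            m0.branch_scale, m0.lnl, m0.pi, 4, m0.n_sequences, m0.n_codons))
        assert res.two_delta_l == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_degrees_of_freedom_by_parameter_counting(self, m1a_dataset):
        m0, m1, m2 = m1a_dataset
        assert st.lrt(m0, m1).df == 1      # {omega} vs {p0, omega0}
        assert st.lrt(m1, m2).df == 2      # adds {p2-structure, omega2}

    def test_non_nested_pair_rejected(self, m1a_dataset):
        m0, _, m2 = m1a_dataset
        with pytest.raises(ValueError):
            st.lrt(m0, m2)
        with pytest.raises(ValueError):
            st.lrt(m2, m0)


def test_fit_table_carries_table_two_columns(m1a_dataset):
    m0, m1, m2 = m1a_dataset
    tests = [st.lrt(m0, m1), st.lrt(m1, m2)]
    nc = st.nc_report(toy_alignment({"a": "ATGAAA", "b": "ATGAAA",
                                     "c": "ATGAAG"}))
    table = st.fit_table([m0, m1, m2], tests, nc)
    assert set(["model", "lnl", "omega0", "p0", "two_delta_l",
                "nc_mean"]) <= set(table.columns)
    assert list(table["model"]) == ["M0", "M1a", "M2a"]
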