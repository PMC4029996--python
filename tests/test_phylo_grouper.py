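"""T92 distances, neighbor joining vs oracles, bootstrap, grouping."""

import numpy as np
import pytest

from delscape import phylo_grouper as pg
from delscape import simdata

from oracles import patristic_matrix, random_additive_matrix


def sequences_with_counts(n=200, transitions=0, transversions=0):
    """A pair with exact substitution counts and pairwise GC of 0.5.

    Base sequence cycles ACGT (theta = 0.5); transitions are applied as
    balanced A->G / C->T swaps and transversions as balanced A->T / G->C
    swaps, so the pair's GC content stays exactly 0.5.
    """
    s1 = ("ACGT" * (n // 4 + 1))[:n]
    s2 = list(s1)
    pos = iter(range(0, n, 4))          # positions holding 'A'
    pos_c = iter(range(1, n, 4))        # positions holding 'C'
    pos_g = iter(range(2, n, 4))        # positions holding 'G'
    for k in range(transitions // 2):
        s2[next(pos)] = "G"             # A->G adds a G
        s2[next(pos_c)] = "T"           # C->T removes a C
    for k in range(transversions // 2):
        s2[next(pos)] = "T"             # A->T, GC unchanged
        s2[next(pos_g)] = "C"           # G->C, GC unchanged
    return s1, "".join(s2)


class TestT92Distance:
    def test_identical_sequences_have_zero_distance(self):
        d, sat = pg.t92_pair("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and not sat

    def test_reduces_to_kimura_two_parameter_at_half_gc(self):
        s1, s2 = sequences_with_counts(400, transitions=40,
                                       transversions=20)
        p, q = 40 / 400, 20 / 400
        k80 = -0.5 * np.log(1 - 2 * p - q) - 0.25 * np.log(1 - 2 * q)
        d, _ = pg.t92_pair(s1, s2)
        assert d == pytest.approx(k80, abs=1e-10)

    def test_hand_evaluated_formula_value(self):
        # P=0.1, Q=0.05, theta=0.4: d = 0.17084431313498982 (independent
        # numeric evaluation of the distance formula)
        s1 = ("AC" * 40 + "GT" * 10)    # 100 bases: 40 A, 40 C, 10 G, 10 T
        s2 = list(s1)
        for k in range(0, 10, 2):       # 10 transitions: 5 A->G, 5 C->T
            s2[2 * k] = "G"
            s2[2 * k + 1] = "T"
        for k in range(10, 15):         # 5 transversions A->T / G->C mix
            s2[2 * k] = "T"
        s2 = "".join(s2)
        pairs = list(zip(s1, s2))
        gc = sum((a in "GC") + (b in "GC") for a, b in pairs) / 200
        # engineered counts can shift composition; recompute expectation
        p = sum({a, b} in ({"A", "G"}, {"C", "T"})
                for a, b in pairs if a != b) / 100
        q = sum(a != b for a, b in pairs) / 100 - p
        h = 2 * gc * (1 - gc)
        expected = -h * np.log(1 - p / h - q) \
            - 0.5 * (1 - h) * np.log(1 - 2 * q)
        d, _ = pg.t92_pair(s1, s2)
        assert d == pytest.approx(expected, abs=1e-12)
        # the frozen reference case
        assert -0.48 * np.log(1 - 0.1 / 0.48 - 0.05) \
            - 0.26 * np.log(0.9) == pytest.approx(0.17084431313498982)

    def test_gamma_variant_exceeds_plain_distance(self):
        s1, s2 = sequences_with_counts(400, transitions=40,
                                       transversions=20)
        d_plain, _ = pg.t92_pair(s1, s2)
        d_gamma, _ = pg.t92_pair(s1, s2, gamma_alpha=1.07)
        assert d_gamma > d_plain

    def test_monotone_in_transition_proportion(self):
        dists = []
        for ts in range(0, 120, 8):
            s1, s2 = sequences_with_counts(800, transitions=ts,
                                           transversions=16)
            dists.append(pg.t92_pair(s1, s2)[0])
        assert all(b >= a for a, b in zip(dists, dists[1:]))

    def test_saturated_pair_flagged_and_ceilinged(self):
        s1 = "A" * 50 + "C" * 50
        s2 = "G" * 50 + "T" * 50        # all transitions: log arg <= 0
        d, sat = pg.t92_pair(s1, s2, ceiling=7.5)
        assert sat and d == 7.5

    def test_pairwise_deletion_of_gap_sites(self):
        d, _ = pg.t92_pair("ACGT-NGT", "ACGTAAGT")
        assert d == 0.0

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError):
            pg.t92_distance({"a": "ACGT", "b": "ACG"})


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        ids, m = random_additive_matrix(4, seed=1)
        tree = pg.nj_tree(pg.DistanceMatrix(ids, m))
        got = patristic_matrix(tree.newick(), ids)
        assert np.allclose(got, m, atol=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = pg.nj_tree(pg.DistanceMatrix(ids, m))
        got = patristic_matrix(tree.newick(), ids)
        assert np.allclose(got, m, atol=1e-9)

    def test_permuting_taxon_order_preserves_topology(self):
        ids, m = random_additive_matrix(8, seed=2)
        perm = [3, 1, 7, 0, 6, 2, 5, 4]
        ids_p = [ids[i] for i in perm]
        m_p = m[np.ix_(perm, perm)]
        d1 = patristic_matrix(pg.nj_tree(pg.DistanceMatrix(ids, m)).newick(),
                              ids)
        d2 = patristic_matrix(
            pg.nj_tree(pg.DistanceMatrix(ids_p, m_p)).newick(), ids)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj
        ids, m = random_additive_matrix(9, seed=3)
        ours = patristic_matrix(pg.nj_tree(pg.DistanceMatrix(ids, m)).newick(),
                                ids)
        theirs_tree = nj(SkDM(m, ids))
        theirs = np.zeros_like(m)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    d = theirs_tree.find(a).distance(theirs_tree.find(b))
                    theirs[i, j] = theirs[j, i] = d
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            pg.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))


def three_family_alignment(seed=0, n_per=4, length=1200):
    """Star-like ingroup: three families with family-diagnostic columns
    only (no between-family signal), plus a distant outgroup pair."""
    rng = np.random.default_rng(seed)
    base = simdata.random_dna(rng, length)
    # disjoint diagnostic blocks: 120 columns per family, 200 for outgroup
    blocks = {"A": (0, 120), "B": (120, 240), "C": (240, 360),
              "out": (360, 560)}
    flip = str.maketrans("ACGT", "GTAC")
    msa = {}
    for fam in "ABC":
        a, b = blocks[fam]
        fam_seq = base[:a] + base[a:b].translate(flip) + base[b:]
        for k in range(n_per):
            msa[f"{fam}{k}"] = simdata._mutate(fam_seq, 0.01, rng)
    a, b = blocks["out"]
    out_seq = base[:a] + base[a:b].translate(flip) + base[b:]
    msa["out1"] = simdata._mutate(out_seq, 0.01, rng)
    msa["out2"] = simdata._mutate(out_seq, 0.01, rng)
    return msa


class TestBootstrap:
    def test_clean_signal_gives_full_support(self):
        # zero-homoplasy alignment: every internal edge of the true tree
        # ((a1,a2),(b1,b2)),((c1,c2),(d1,d2)) has its own diagnostic block
        rng = np.random.default_rng(4)
        base = simdata.random_dna(rng, 1400)
        flip = str.maketrans("ACGT", "GTAC")

        def flipped(seq, a, b):
            return seq[:a] + seq[a:b].translate(flip) + seq[b:]

        pair_blocks = {"a": (0, 150), "b": (150, 300), "c": (300, 450),
                       "d": (450, 600)}
        ab_block = (600, 750)
        leaf_blocks = {}
        pos = 750
        msa = {}
        for fam in "abcd":
            for k in (1, 2):
                seq = flipped(base, *pair_blocks[fam])
                if fam in "ab":
                    seq = flipped(seq, *ab_block)
                seq = flipped(seq, pos, pos + 30)   # private terminal block
                pos += 30
                msa[f"{fam}{k}"] = seq
        tree = pg.bootstrap_support(msa, n_reps=30, seed=1)
        sups = [c for c in _all_supports(tree) if c is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = three_family_alignment(seed=5, length=300)
        tree = pg.bootstrap_support(msa, n_reps=1, seed=2)
        sups = {s for s in _all_supports(tree) if s is not None}
        assert sups <= {0.0, 100.0}

    def test_fixed_seed_reproduces_support_vector(self):
        msa = three_family_alignment(seed=6, length=400)
        t1 = pg.bootstrap_support(msa, n_reps=20, seed=7)
        t2 = pg.bootstrap_support(msa, n_reps=20, seed=7)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)


def _all_supports(clade):
    out = [clade.support]
    for child, _ in clade.children:
        out.extend(_all_supports(child))
    return out


class TestAssignGroups:
    def test_three_simulated_families_recovered_as_three_groups(self):
        msa = three_family_alignment(seed=8, length=2000)
        tree = pg.bootstrap_support(msa, n_reps=30, seed=3)
        assignment = pg.assign_groups(tree, ["out1", "out2"])
        labels = {}
        for taxon, group in assignment.groups.items():
            if group not in ("outgroup",):
                labels.setdefault(group, set()).add(taxon[0])
        families = [v for v in labels.values()]
        assert len(labels) == 3
        assert all(len(v) == 1 for v in families)

    def test_threshold_above_hundred_groups_nothing(self):
        msa = three_family_alignment(seed=9, length=1000)
        tree = pg.bootstrap_support(msa, n_reps=10, seed=4)
        assignment = pg.assign_groups(tree, ["out1", "out2"],
                                      min_support=101)
        ingroup = {t: g for t, g in assignment.groups.items()
                   if g != "outgroup"}
        assert set(ingroup.values()) == {"ungrouped"}

    def test_support_exactly_at_threshold_is_excluded(self):
        # clade (a,b) at support exactly 75; parent too weak to group
        newick = "(((a:1,b:1)75:1,(c:1,d:1)99:1)50:1,out:1);"
        assignment = pg.assign_groups(newick, ["out"], min_support=75)
        assert assignment.groups["a"] == "ungrouped"
        assert assignment.groups["b"] == "ungrouped"
        assert assignment.groups["c"] == assignment.groups["d"] != "ungrouped"

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError):
            pg.assign_groups("((a:1,b:1)90:1,c:1);", ["zzz"])

    def test_groups_numbered_with_roman_numerals_depth_first(self):
        newick = "(((a:1,b:1)99:1,(c:1,d:1)99:1)100:1,out:1);"
        assignment = pg.assign_groups(newick, ["out"])
        assert set(assignment.supports) <= {"I", "II"}
        assert len(set(assignment.groups.values()) - {"outgroup"}) >= 1


def test_nj_recovers_generating_tree_on_many_random_additive_matrices():
    for seed in range(20):
        n = 4 + seed % 6
        ids, m = random_additive_matrix(n, seed=100 + seed)
        tree = pg.nj_tree(pg.DistanceMatrix(ids, m))
        got = patristic_matrix(tree.newick(), ids)
        assert np.allclose(got, m, atol=1e-8), f"seed {seed}"
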