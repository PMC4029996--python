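"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (direct enumeration, scipy expm,
per-window string counting) and shares no code path with the package
internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

GENETIC_CODE_TABLE = None  # filled lazily from Biopython to stay independent


# ---------------------------------------------------------------------------
# CpG island brute force

def brute_force_islands(seq, window=100, min_len=200, min_gc=50.0,
                        min_oe=0.6):
    """Naive per-window scan; returns (covered_flags, islands) where each
    island is (start, end, mean_gc, mean_oe)."""
    seq = seq.upper()
    n = len(seq)
    if n < window:
        return np.zeros(n, dtype=bool), []
    stats = []
    for s in range(n - window + 1):
        w = seq[s:s + window]
        c, g = w.count("C"), w.count("G")
        gc = 100.0 * (c + g) / window
        oe = (w.count("CG") * window / (c * g)) if c and g else 0.0
        stats.append((s, gc, oe, gc >= min_gc and oe >= min_oe))
    covered = np.zeros(n, dtype=bool)
    for s, _, _, ok in stats:
        if ok:
            covered[s:s + window] = True
    islands = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < n and covered[j]:
            j += 1
        if j - i >= min_len:
            overl = [(gc, oe) for s, gc, oe, ok in stats
                     if ok and s < j and s + window > i]
            islands.append((i, j,
                            float(np.mean([x[0] for x in overl])),
                            float(np.mean([x[1] for x in overl]))))
        i = j
    return covered, islands


# ---------------------------------------------------------------------------
# exact motif scan brute force

def naive_motif_scan(seq, motif):
    """O(n*m) sliding comparison on both strands; (pos, strand) tuples."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(motif))
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        win = seq[i:i + len(motif)]
        if all(a == b for a, b in zip(win, motif)):
            hits.append((i, "+"))
        if all(a == b for a, b in zip(win, rc)):
            hits.append((i, "-"))
    return hits


# ---------------------------------------------------------------------------
# random additive distance matrices (four-point-condition generator)

def random_additive_matrix(n_taxa, seed):
    """Random binary tree with positive branch lengths; returns
    (taxon ids, additive distance matrix)."""
    rng = np.random.default_rng(seed)
    ids = [f"x{i}" for i in range(n_taxa)]
    # each cluster: dict leaf -> distance to cluster root
    clusters = [{ids[i]: 0.0} for i in range(n_taxa)]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        bi, bj = rng.uniform(0.1, 1.0, size=2)
        a, b = clusters[i], clusters[j]
        for la, da in a.items():
            for lb, db in b.items():
                dist[frozenset((la, lb))] = da + bi + db + bj
        merged = {l: d + bi for l, d in a.items()}
        merged.update({l: d + bj for l, d in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    m = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            m[a, b] = m[b, a] = dist[frozenset((ids[a], ids[b]))]
    return ids, m


def patristic_matrix(newick, ids):
    """Leaf-to-leaf path lengths of a newick tree, via dendropy."""
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    n = len(ids)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = pdm.patristic_distance(ns.get_taxon(ids[a]),
                                       ns.get_taxon(ids[b]))
            out[a, b] = out[b, a] = d
    return out


# ---------------------------------------------------------------------------
# codon model brute force

def gy_rate_matrix(kappa, omega, pi, codons, code):
    """Direct enumeration of the sense-codon rate matrix, scaled to mean
    rate one (independent of the package's construction)."""
    n = len(codons)
    q = np.zeros((n, n))
    transitions = ({"A", "G"}, {"C", "T"})
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(codons[i], codons[j]) if a != b]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if set(diffs[0]) in transitions:
                rate *= kappa
            if code[codons[i]] != code[codons[j]]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale


def two_taxon_loglike(seq_a, seq_b, t_a, t_b, kappa, omega, pi):
    """Brute-force pairwise likelihood: sum over the unknown ancestor,
    P(t) by scipy matrix exponential."""
    from Bio.Data.CodonTable import standard_dna_table
    stops = set(standard_dna_table.stop_codons)
    code = dict(standard_dna_table.forward_table)
    bases = "ACGT"
    codons = sorted("".join((a, b, c)) for a in bases for b in bases
                    for c in bases if a + b + c not in stops)
    idx = {c: k for k, c in enumerate(codons)}
    q = gy_rate_matrix(kappa, omega, pi, codons, code)
    pa, pb = expm(q * t_a), expm(q * t_b)
    lnl = 0.0
    for i in range(0, len(seq_a), 3):
        x, y = idx[seq_a[i:i + 3]], idx[seq_b[i:i + 3]]
        lnl += np.log((pi * pa[:, x] * pb[:, y]).sum())
    return lnl


def ng86_dn_ds(seq_a, seq_b):
    """Nei–Gojobori-style counting estimate of dN/dS (proportion-based,
    no multiple-hit correction; codons differing at >1 position average
    over minimal pathways)."""
    from Bio.Data.CodonTable import standard_dna_table
    from itertools import permutations
    stops = set(standard_dna_table.stop_codons)
    code = dict(standard_dna_table.forward_table)

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt in stops:
                    continue
                if code[alt] == code[codon]:
                    s += 1.0 / 3.0
        return s

    def path_counts(c1, c2):
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        results = []
        for order in permutations(diffs):
            cur, sd, nd, valid = c1, 0.0, 0.0, True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                if nxt in stops:
                    valid = False
                    break
                if code.get(cur, "*") == code.get(nxt, "*"):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if valid:
                results.append((sd, nd))
        if not results:
            return 0.0, float(len(diffs))
        return (float(np.mean([r[0] for r in results])),
                float(np.mean([r[1] for r in results])))

    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        c1, c2 = seq_a[i:i + 3], seq_b[i:i + 3]
        if c1 in stops or c2 in stops:
            continue
        s1, s2 = syn_sites(c1), syn_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        if c1 != c2:
            dsd, dnd = path_counts(c1, c2)
            sd += dsd
            nd += dnd
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return (pn / ps) if ps > 0 else float("inf")
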