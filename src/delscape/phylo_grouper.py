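"""Neighbor-joining phylogenies from Tamura 3-parameter distances, with
bootstrap supports and support-thresholded group assignment.

The Tamura 3-parameter model corrects pairwise distances for unequal
transition/transversion rates and G+C-content bias; the gamma variant
additionally allows rate variation across sites (shape ``a``).  With P the
transition proportion, Q the transversion proportion, theta the G+C
content of the sequence pair and h = 2*theta*(1-theta):

    d = -h ln(1 - P/h - Q) - (1-h)/2 ln(1 - 2Q)
    d_gamma = a { h[(1 - P/h - Q)^(-1/a) - 1] + (1-h)/2 [(1-2Q)^(-1/a) - 1] }

Gap/N sites are removed pairwise.  Trees are built with the Saitou–Nei
neighbor-joining algorithm with deterministic tie-breaking (smallest
taxon-index pair) and negative branch lengths clamped to zero.  Groups are
the maximal ingroup clades whose bootstrap support strictly exceeds the
threshold, numbered with roman numerals in depth-first order from the
root (the classification used to delimit retroelement groups).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = {"A", "C", "G", "T"}


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    saturated: np.ndarray | None = None   # boolean mask of ceiling entries

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match taxon count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def t92_pair(seq1: str, seq2: str, gamma_alpha: float | None = None,
             ceiling: float = 10.0) -> tuple[float, bool]:
    """T92 distance for one pair; returns (distance, saturated_flag)."""
    pairs = [(a, b) for a, b in zip(seq1.upper(), seq2.upper())
             if a in VALID and b in VALID]
    if not pairs:
        return ceiling, True
    n = len(pairs)
    transitions = transversions = gc = 0
    for a, b in pairs:
        gc += (a in "GC") + (b in "GC")
        if a == b:
            continue
        if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
            transitions += 1
        else:
            transversions += 1
    p, q = transitions / n, transversions / n
    theta = gc / (2 * n)
    h = 2.0 * theta * (1.0 - theta)
    if h == 0.0:
        h = 1e-12      # degenerate pair with no (or all) G+C content
    arg1 = 1.0 - p / h - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return ceiling, True
    if gamma_alpha is None:
        d = -h * np.log(arg1) - 0.5 * (1.0 - h) * np.log(arg2)
    else:
        a_ = gamma_alpha
        d = a_ * (h * (arg1 ** (-1.0 / a_) - 1.0)
                  + 0.5 * (1.0 - h) * (arg2 ** (-1.0 / a_) - 1.0))
    return max(0.0, float(d)), False


def t92_distance(msa: dict[str, str] | list[tuple[str, str]],
                 gamma_alpha: float | None = None,
                 ceiling: float = 10.0) -> DistanceMatrix:
    """Pairwise T92(+gamma) distance matrix with pairwise gap deletion."""
    items = list(msa.items()) if isinstance(msa, dict) else list(msa)
    ids = [name for name, _ in items]
    seqs = [seq for _, seq in items]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned to equal length")
    n = len(ids)
    m = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, s = t92_pair(seqs[i], seqs[j], gamma_alpha, ceiling)
            m[i, j] = m[j, i] = d
            sat[i, j] = sat[j, i] = s
    if sat.any():
        print(f"[phylo_grouper] {int(sat.sum() // 2)} saturated pair(s) "
              f"set to ceiling {ceiling}", file=sys.stderr)
    return DistanceMatrix(ids, m, sat)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class Clade:
    label: str | None = None
    children: list[tuple["Clade", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._nwk(ws)}:{b:.6f}" for c, b in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}"


def nj_tree(dm: DistanceMatrix) -> Clade:
    """Saitou–Nei neighbor joining; unrooted (trifurcating root for n>=3).

    Ties in the Q criterion break on the smallest (min original taxon
    index) pair; negative branch lengths are clamped to zero.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = {i: Clade(label=name) for i, name in enumerate(dm.ids)}
    rank = {i: i for i in range(n)}      # min original index per cluster
    d = {(i, j): dm.matrix[i, j] for i in range(n) for j in range(i + 1, n)}

    def dist(i, j):
        return d[(i, j) if i < j else (j, i)]

    active = set(range(n))
    next_id = n
    clamped = 0
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for i in sorted(active, key=lambda x: rank[x]):
            for j in sorted(active, key=lambda x: rank[x]):
                if rank[j] <= rank[i]:
                    continue
                qv = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (qv, rank[i], rank[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0 or bj < 0:
            clamped += 1
        bi, bj = max(0.0, bi), max(0.0, bj)
        new = Clade(children=[(nodes[i], bi), (nodes[j], bj)])
        nodes[next_id] = new
        rank[next_id] = min(rank[i], rank[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(k, next_id), max(k, next_id))] = max(0.0, dk)
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1

    rest = sorted(active, key=lambda x: rank[x])
    if len(rest) == 2:
        i, j = rest
        dij = dist(i, j)
        root = Clade(children=[(nodes[i], dij / 2), (nodes[j], dij / 2)])
    else:
        root = nodes[rest[0]]
    if clamped:
        print(f"[phylo_grouper] {clamped} negative branch length(s) "
              "clamped to 0", file=sys.stderr)
    return root


def _splits(root: Clade, all_taxa: frozenset[str]) -> dict[frozenset, float | None]:
    """Non-trivial bipartitions below each internal edge, canonicalised as
    the side not containing the lexicographically first taxon."""
    ref = min(all_taxa)
    out: dict[frozenset, float | None] = {}

    def walk(node: Clade):
        for child, _ in node.children:
            leaves = frozenset(child.leaves())
            if 1 < len(leaves) < len(all_taxa) - 1:
                side = leaves if ref not in leaves else all_taxa - leaves
                out[side] = child.support
            walk(child)

    walk(root)
    return out


def bootstrap_support(msa: dict[str, str], n_reps: int = 100, seed: int = 0,
                      gamma_alpha: float | None = None) -> Clade:
    """NJ tree on the full alignment with per-edge bootstrap percentages.

    Columns are resampled with replacement per replicate; an edge's
    support is the percentage of replicate trees containing the same
    bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = list(msa)
    seqs = [msa[t] for t in ids]
    ncol = len(seqs[0])
    full = nj_tree(t92_distance(msa, gamma_alpha))
    taxa = frozenset(ids)
    target = _splits(full, taxa)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    arr = np.array([list(s) for s in seqs])
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_msa = {t: "".join(arr[k][cols]) for k, t in enumerate(ids)}
        rep_tree = nj_tree(t92_distance(rep_msa, gamma_alpha))
        rep_splits = _splits(rep_tree, taxa)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    def annotate(node: Clade):
        for child, _ in node.children:
            leaves = frozenset(child.leaves())
            if 1 < len(leaves) < len(taxa) - 1:
                ref = min(taxa)
                side = leaves if ref not in leaves else taxa - leaves
                child.support = 100.0 * counts[side] / n_reps
            annotate(child)

    annotate(full)
    return full


# ---------------------------------------------------------------------------
# group assignment

def _roman(k: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
                (100, "C"), (90, "XC"), (50, "L"), (40, "XL"), (10, "X"),
                (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for value, sym in numerals:
        while k >= value:
            out += sym
            k -= value
    return out


@dataclass
class GroupAssignment:
    groups: dict[str, str]          # taxon -> group label ('ungrouped' too)
    supports: dict[str, float]      # group label -> bootstrap support

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"taxon": t, "group": g,
              "support": self.supports.get(g, float("nan"))}
             for t, g in sorted(self.groups.items())])


def assign_groups(tree: Clade | str, outgroup_ids, min_support: float = 75.0
                  ) -> GroupAssignment:
    """Maximal ingroup clades with support strictly above the threshold.

    The tree (a Clade with supports, or its Newick string) is rooted on
    the outgroup; groups are numbered with roman numerals in depth-first
    order from the root.  Ingroup taxa not inside any qualifying clade
    are labelled 'ungrouped'.
    """
    newick = tree.newick(with_support=True) if isinstance(tree, Clade) \
        else tree
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    dtree.is_rooted = True
    taxa = {leaf.taxon.label for leaf in dtree.leaf_node_iter()}
    outgroup = set(outgroup_ids)
    if not outgroup <= taxa:
        raise ValueError(f"outgroup taxa missing: {sorted(outgroup - taxa)}")
    if outgroup == taxa:
        raise ValueError("no ingroup taxa")
    # supports belong to bipartitions, not nodes: record them before
    # rerooting (which re-attaches internal labels to the wrong edges)
    ref = min(taxa)

    def canonical(leafset: frozenset) -> frozenset:
        return leafset if ref not in leafset else frozenset(taxa) - leafset

    split_support: dict[frozenset, float] = {}
    for node in dtree.preorder_internal_node_iter():
        if node.label is None:
            continue
        try:
            sup = float(node.label)
        except ValueError:
            continue
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        split_support[canonical(leafset)] = sup

    mrca = dtree.mrca(taxon_labels=sorted(outgroup)) if len(outgroup) > 1 \
        else dtree.find_node_with_taxon_label(next(iter(outgroup)))
    if mrca.parent_node is not None:
        dtree.reroot_at_edge(mrca.edge, update_bipartitions=False)

    groups: dict[str, str] = {}
    supports: dict[str, float] = {}
    counter = [0]

    def support_of(node) -> float | None:
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        return split_support.get(canonical(leafset))

    n_ingroup = len(taxa - outgroup)

    def walk(node):
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if any(t in outgroup for t in leaves) or len(leaves) == n_ingroup:
            # mixed clades and the full ingroup crown are containers,
            # not groups — descend
            for child in node.child_nodes():
                walk(child)
            return
        sup = support_of(node)
        if sup is not None and sup > min_support and len(leaves) > 1:
            counter[0] += 1
            label = _roman(counter[0])
            supports[label] = sup
            for t in leaves:
                groups[t] = label
            return
        if node.is_leaf():
            groups[leaves[0]] = "ungrouped"
            return
        for child in node.child_nodes():
            walk(child)

    walk(dtree.seed_node)
    for t in taxa - outgroup:
        groups.setdefault(t, "ungrouped")
    for t in outgroup:
        groups[t] = "outgroup"
    return GroupAssignment(groups, supports)
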