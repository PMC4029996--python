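"""Goldman–Yang-style codon substitution machinery on the 61 sense codons.

The rate matrix follows the classic parameterisation: instantaneous change is
allowed only between codons differing at a single nucleotide position, and the
rate from codon i to codon j is proportional to

    pi_j                synonymous transversion
    kappa * pi_j        synonymous transition
    omega * pi_j        nonsynonymous transversion
    omega * kappa * pi_j  nonsynonymous transition

with ``pi`` the equilibrium codon frequencies (F3x4 or explicit) and the
matrix rescaled so the expected number of substitutions per codon per unit
branch length equals one.  Because the process is time-reversible the
transition matrices are computed through a symmetric eigendecomposition,
which is both faster and numerically safer than a general matrix exponential.
"""

from __future__ import annotations

import itertools

import numpy as np

from ._seq import DNA

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = tuple(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(DNA, repeat=3)
    if GENETIC_CODE["".join(c)] != "*"
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
CODON_AA = tuple(GENETIC_CODE[c] for c in SENSE_CODONS)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _single_change_masks() -> tuple[np.ndarray, np.ndarray]:
    """Boolean (61,61) masks: single-nucleotide transitions / transversions."""
    ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    tv = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            if frozenset(diffs[0]) in _TRANSITIONS:
                ts[i, j] = True
            else:
                tv[i, j] = True
    return ts, tv


_TS_MASK, _TV_MASK = _single_change_masks()
_SYN_MASK = np.array(
    [[CODON_AA[i] == CODON_AA[j] for j in range(N_CODONS)] for i in range(N_CODONS)]
)


def f3x4_frequencies(seqs, floor: float = 1e-6) -> np.ndarray:
    """Equilibrium codon frequencies from position-specific nucleotide counts.

    ``seqs`` is an iterable of in-frame nucleotide strings (no gaps).  Each
    codon's frequency is the product of its three nucleotides' frequencies at
    the corresponding codon position, renormalised over the 61 sense codons.
    Nucleotide frequencies are floored to keep every sense codon reachable.
    """
    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(DNA)}
    for seq in seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            for pos in range(3):
                b = seq[i + pos]
                if b in base_idx:
                    counts[pos, base_idx[b]] += 1
    if counts.sum() == 0:
        raise ValueError("no codons observed")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, floor)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array([
        freqs[0, base_idx[c[0]]] * freqs[1, base_idx[c[1]]] * freqs[2, base_idx[c[2]]]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled instantaneous rate matrix Q (mean rate one substitution/codon)."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    rates = np.where(_TS_MASK, kappa, 0.0) + np.where(_TV_MASK, 1.0, 0.0)
    rates = np.where(_SYN_MASK, rates, rates * omega)
    q = rates * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix")
    return q / mean_rate


class CodonProcess:
    """Eigendecomposed reversible codon process for fast P(t) evaluation."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        self.q = rate_matrix(kappa, omega, self.pi)
        sqrt_pi = np.sqrt(self.pi)
        sym = self.q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = (sym + sym.T) / 2.0  # enforce symmetry against round-off
        self.eigvals, eigvecs = np.linalg.eigh(sym)
        self._left = eigvecs / sqrt_pi[:, None]
        self._right = eigvecs * sqrt_pi[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) with P[i, j] = Pr(j at time t | i at time 0)."""
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._left * np.exp(self.eigvals * t)) @ self._right.T
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]
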