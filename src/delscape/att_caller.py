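"""Attachment-site discovery from the terminal 40 bp of LTR sets.

The integrase of Ty3/Gypsy elements recognises short cis motifs at the LTR
termini: a 10-bp U3 att opening the LTR and an 11-bp U5 att closing it.
This module profiles the first and last 40 bases of an LTR set (base
counts and per-position information content, logo-style), calls the att
consensi with IUPAC ambiguity at ties, quantifies their conservation as
100 x (1 - mean pairwise p-distance) over the att window, and types U5
atts by the diagnostic triplet at positions -8, -9, -10 (GGG = type A,
TTC = type B; -1 is the final base of the LTR, the A of the terminal CA).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import DNA, IUPAC

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class TerminalProfile:
    end: str                      # five_prime | three_prime
    counts: np.ndarray            # (width, 4) base counts over A,C,G,T
    information: np.ndarray       # (width,) bits in [0, 2]
    windows: list[str]            # the terminal width-mers actually profiled

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return len(self.windows)


@dataclass
class AttCall:
    u3_seq: str
    u5_seq: str
    u3_mean_identity: float       # percent
    u5_mean_identity: float
    u5_type: str


def terminal_profile(ltrs, end: str, width: int = 40,
                     small_sample_correction: bool = False) -> TerminalProfile:
    """Per-position base counts and information content of one LTR end.

    The 3' profile covers the last ``width`` bases in plus-strand
    coordinates (column ``width-1`` is the LTR's final base).  LTRs
    shorter than ``width`` are skipped with a warning.
    """
    if end not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError("end must be five_prime or three_prime")
    windows = []
    for seq in ltrs:
        seq = str(seq).upper()
        if len(seq) < width:
            warnings.warn(f"LTR of {len(seq)} bp shorter than {width}; skipped")
            continue
        windows.append(seq[:width] if end == FIVE_PRIME else seq[-width:])
    if not windows:
        raise ValueError("no LTR reaches the profile width")
    counts = np.zeros((width, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(DNA)}
    for w in windows:
        for i, b in enumerate(w):
            if b in base_idx:
                counts[i, base_idx[b]] += 1
    totals = counts.sum(axis=1)
    info = np.zeros(width)
    for i in range(width):
        if totals[i] == 0:
            continue
        p = counts[i] / totals[i]
        nz = p[p > 0]
        entropy = -(nz * np.log2(nz)).sum()
        correction = 3.0 / (2.0 * np.log(2) * totals[i]) \
            if small_sample_correction else 0.0
        info[i] = max(0.0, 2.0 - entropy - correction)
    return TerminalProfile(end, counts, info, windows)


def _consensus(counts: np.ndarray) -> str:
    out = []
    for row in counts:
        if row.sum() == 0:
            out.append("N")
            continue
        top = row.max()
        out.append(IUPAC[frozenset(DNA[i] for i in range(4)
                                   if row[i] == top)])
    return "".join(out)


def _mean_pairwise_identity(counts: np.ndarray) -> float:
    """Mean pairwise per-site identity over a window, from column counts.

    Equals the all-pairs average: per column, the probability two distinct
    sequences agree is sum_b c_b(c_b - 1) / (n(n - 1)).
    """
    idents = []
    for row in counts:
        n = row.sum()
        if n < 2:
            continue
        idents.append((row * (row - 1)).sum() / (n * (n - 1)))
    if not idents:
        raise ValueError("need at least two sequences for pairwise identity")
    return float(np.mean(idents))


def mean_p_distance(counts: np.ndarray) -> float:
    return 1.0 - _mean_pairwise_identity(counts)


def call_att(profile5: TerminalProfile, profile3: TerminalProfile) -> AttCall:
    """Call the 10-bp U3 and 11-bp U5 atts from the two terminal profiles."""
    if profile5.end != FIVE_PRIME or profile3.end != THREE_PRIME:
        raise ValueError("expected a 5' and a 3' profile, in that order")
    u3_counts = profile5.counts[:10]
    u5_counts = profile3.counts[-11:]
    u3 = _consensus(u3_counts)
    u5 = _consensus(u5_counts)
    return AttCall(
        u3_seq=u3,
        u5_seq=u5,
        u3_mean_identity=100.0 * _mean_pairwise_identity(u3_counts),
        u5_mean_identity=100.0 * _mean_pairwise_identity(u5_counts),
        u5_type=type_u5(u5),
    )


def type_u5(u5_seq: str) -> str:
    """Type an 11-bp U5 att by positions -8,-9,-10 (GGG -> A, TTC -> B)."""
    if len(u5_seq) != 11:
        raise ValueError("U5 att must be 11 bp")
    triplet = u5_seq[1:4].upper()  # plus-strand offsets -10,-9,-8
    if any(b not in DNA for b in triplet):
        return "other"
    if triplet == "GGG":
        return "A"
    if triplet == "TTC":
        return "B"
    return "other"


def profile_table(profile: TerminalProfile) -> pd.DataFrame:
    """Logo-ready per-position matrix (counts, frequencies, information)."""
    totals = profile.counts.sum(axis=1)
    rows = []
    for i in range(profile.width):
        row = {"position": i + 1 if profile.end == FIVE_PRIME
               else i - profile.width}
        for j, b in enumerate(DNA):
            row[f"count_{b}"] = profile.counts[i, j]
            row[f"freq_{b}"] = (profile.counts[i, j] / totals[i]
                                if totals[i] else 0.0)
        row["information_bits"] = profile.information[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_att_report(call: AttCall, profile5: TerminalProfile,
                     profile3: TerminalProfile, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame([{
        "u3_seq": call.u3_seq, "u5_seq": call.u5_seq,
        "u3_mean_identity": round(call.u3_mean_identity, 2),
        "u5_mean_identity": round(call.u5_mean_identity, 2),
        "u5_type": call.u5_type, "n_ltrs": profile5.n,
    }]).to_csv(f"{prefix}.att.tsv", sep="\t", index=False)
    profile_table(profile5).to_csv(f"{prefix}.profile5.tsv", sep="\t",
                                   index=False)
    profile_table(profile3).to_csv(f"{prefix}.profile3.tsv", sep="\t",
                                   index=False)
    print(f"[att_caller] U3={call.u3_seq} U5={call.u5_seq} "
          f"type={call.u5_type}", file=sys.stderr)
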