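"""Structural mining of full-length LTR retroelements from raw chromosomes.

Candidate elements are found purely structurally: two long, co-linear,
highly similar direct repeats (the LTR pair) at a plausible separation,
refined so the 5' LTR starts with TG and the 3' LTR ends with CA, with the
4-6 bp target-site duplication read off the flanks when present.  The
detector is a transparent seed-and-extend scheme: exact k-mer seeds shared
between the two prospective LTR copies are grouped by diagonal, extended
with an X-drop ungapped walk, and verified with a gapped edit-distance
alignment (edlib) for the identity threshold.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import encode


@dataclass(frozen=True)
class MinerParams:
    min_ltr_len: int = 1000
    max_ltr_len: int = 5000
    min_separation: int = 1000      # inter-LTR (internal region) span, bp
    max_separation: int = 15000
    min_identity: float = 0.80
    kmer: int = 15
    tsd_range: tuple[int, int] = (4, 6)
    slack: int = 15                 # terminus search window, bp
    min_seeds: int = 3
    xdrop: int = 20

    def __post_init__(self):
        if not (0 < self.min_ltr_len < self.max_ltr_len):
            raise ValueError("need 0 < min_ltr_len < max_ltr_len")
        if not (0 < self.min_separation < self.max_separation):
            raise ValueError("need 0 < min_separation < max_separation")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0,1]")


@dataclass
class LTRCandidate:
    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float
    tsd: str = ""
    termini_ok: bool = False


@dataclass
class RepeatPair:
    """Approximate co-linear direct repeat: two equal-diagonal intervals."""
    start1: int
    end1: int
    start2: int
    end2: int
    identity: float = 0.0


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer codes and the positions where no N falls in the window."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.uint64)
    clean = np.minimum(codes, 3).astype(np.uint64)
    for t in range(k):
        vals = vals * np.uint64(4) + clean[t:t + n]
    bad = (codes == 4).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    ok = (cum[k:] - cum[:-k]) == 0
    pos = np.flatnonzero(ok)
    return vals[pos], pos


def _alignment_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def find_direct_repeats(seq: str, params: MinerParams | None = None
                        ) -> list[RepeatPair]:
    """Maximal same-strand repeat pairs within the length/separation bounds.

    Seeds never cross Ns; seed pairs are grouped by exact diagonal, so
    repeat copies are assumed co-linear (substitution-level divergence).
    """
    params = params or MinerParams()
    seq = seq.upper()
    codes = encode(seq)
    vals, pos = _kmer_codes(codes, params.kmer)
    if vals.size == 0:
        return []
    order = np.argsort(vals, kind="stable")
    vals, pos = vals[order], pos[order]
    run_starts = np.flatnonzero(np.concatenate([[True], vals[1:] != vals[:-1]]))
    run_lengths = np.diff(np.concatenate([run_starts, [vals.size]]))
    multi = run_starts[(run_lengths >= 2) & (run_lengths <= 64)]
    multi_len = run_lengths[(run_lengths >= 2) & (run_lengths <= 64)]

    lo_diag = params.min_ltr_len + params.min_separation
    hi_diag = params.max_ltr_len + params.max_separation
    by_diag: dict[int, list[int]] = {}
    for start, length in zip(multi, multi_len):
        g = np.sort(pos[start:start + length])
        for ai in range(len(g)):
            for bi in range(ai + 1, len(g)):
                d = int(g[bi] - g[ai])
                if lo_diag <= d <= hi_diag:
                    by_diag.setdefault(d, []).append(int(g[ai]))

    pairs: list[RepeatPair] = []
    for d, starts in sorted(by_diag.items()):
        starts.sort()
        # split seed runs separated by more than max_ltr_len into clusters
        clusters: list[list[int]] = [[starts[0]]]
        for s in starts[1:]:
            if s - clusters[-1][-1] > params.max_ltr_len:
                clusters.append([s])
            else:
                clusters[-1].append(s)
        for cluster in clusters:
            if len(cluster) < params.min_seeds:
                continue
            s = cluster[0]
            e = cluster[-1] + params.kmer
            s, e = _xdrop_extend(codes, s, e, d, params.xdrop)
            length = e - s
            sep = d - length
            if not params.min_ltr_len <= length <= params.max_ltr_len:
                continue
            if not params.min_separation <= sep <= params.max_separation:
                continue
            identity = _alignment_identity(seq[s:e], seq[s + d:e + d])
            if identity >= params.min_identity:
                pairs.append(RepeatPair(s, e, s + d, e + d, identity))
    return pairs


def _xdrop_extend(codes: np.ndarray, s: int, e: int, diag: int,
                  xdrop: int) -> tuple[int, int]:
    """Ungapped X-drop extension of [s,e) vs [s+diag,e+diag) on both ends."""
    n = codes.size
    # leftward
    best, score, best_s = 0, 0, s
    i = s - 1
    while i >= 0 and i + diag < n:
        score += 1 if (codes[i] == codes[i + diag] and codes[i] != 4) else -2
        if score > best:
            best, best_s = score, i
        if best - score > xdrop:
            break
        i -= 1
    # rightward
    best, score, best_e = 0, 0, e
    j = e
    while j + diag < n:
        score += 1 if (codes[j] == codes[j + diag] and codes[j] != 4) else -2
        if score > best:
            best, best_e = score, j + 1
        if best - score > xdrop:
            break
        j += 1
    return best_s, best_e


def refine_candidate(seq: str, pair: RepeatPair, chrom: str = "chr",
                     params: MinerParams | None = None) -> LTRCandidate:
    """Anchor boundaries on TG...CA and read the TSD off the flanks.

    Both LTR copies are shifted by the same offset so they stay co-linear;
    a candidate whose termini cannot be anchored keeps its seeded
    boundaries with ``termini_ok=False`` rather than being dropped.
    """
    params = params or MinerParams()
    n = len(seq)
    if not (0 <= pair.start1 < pair.end1 <= n
            and 0 <= pair.start2 < pair.end2 <= n):
        raise ValueError("repeat pair out of sequence bounds")
    diag = pair.start2 - pair.start1

    def find_shift(target: str, anchor1: int, anchor2: int, at_end: bool):
        offs = sorted(range(-params.slack, params.slack + 1), key=abs)
        for off in offs:
            p1, p2 = anchor1 + off, anchor2 + off
            if at_end:
                w1, w2 = seq[p1 - 2:p1], seq[p2 - 2:p2]
            else:
                w1, w2 = seq[p1:p1 + 2], seq[p2:p2 + 2]
            if w1 == target and w2 == target:
                return off
        return None

    start_off = find_shift("TG", pair.start1, pair.start2, at_end=False)
    end_off = find_shift("CA", pair.end1, pair.end2, at_end=True)
    s1 = pair.start1 + (start_off or 0)
    e1 = pair.end1 + (end_off or 0)
    s2, e2 = s1 + diag, e1 + diag
    termini_ok = start_off is not None and end_off is not None

    tsd = ""
    lo, hi = params.tsd_range
    for length in range(hi, lo - 1, -1):
        if s1 - length < 0 or e2 + length > n:
            continue
        left, right = seq[s1 - length:s1], seq[e2:e2 + length]
        if left == right and "N" not in left:
            tsd = left
            break

    identity = _alignment_identity(seq[s1:e1], seq[s2:e2])
    return LTRCandidate(chrom, s1, e2, (s1, e1), (s2, e2), identity, tsd,
                        termini_ok)


def mine(genome: dict[str, str] | str | Path,
         params: MinerParams | None = None) -> list[LTRCandidate]:
    """Per-chromosome candidates, deduplicated by identity then position."""
    params = params or MinerParams()
    if not isinstance(genome, dict):
        path = Path(genome)
        if not path.exists():
            raise FileNotFoundError(path)
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(path), "fasta")}
        if not genome:
            raise ValueError(f"no sequences in {path}")
    candidates: list[LTRCandidate] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        refined = [refine_candidate(seq, pair, chrom, params)
                   for pair in find_direct_repeats(seq, params)]
        refined = [c for c in refined if c.ltr_identity >= params.min_identity]
        candidates.extend(_dedupe(refined))
    return candidates


def _dedupe(cands: list[LTRCandidate]) -> list[LTRCandidate]:
    """Resolve overlapping candidates: best identity wins, ties leftmost."""
    kept: list[LTRCandidate] = []
    for c in sorted(cands, key=lambda c: (-c.ltr_identity, c.start)):
        if all(c.end <= k.start or c.start >= k.end for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: c.start)


def candidates_table(cands: list[LTRCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "start": c.start, "end": c.end,
        "ltr5_start": c.ltr5[0], "ltr5_end": c.ltr5[1],
        "ltr3_start": c.ltr3[0], "ltr3_end": c.ltr3[1],
        "ltr_identity": round(c.ltr_identity, 4), "tsd": c.tsd,
        "termini_ok": c.termini_ok,
    } for c in cands], columns=[
        "chrom", "start", "end", "ltr5_start", "ltr5_end", "ltr3_start",
        "ltr3_end", "ltr_identity", "tsd", "termini_ok"])


def write_candidates(cands: list[LTRCandidate], prefix: str | Path) -> None:
    prefix = Path(prefix)
    candidates_table(cands).to_csv(prefix.with_suffix(".tsv"), sep="\t",
                                   index=False)
    with open(prefix.with_suffix(".bed"), "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for c in cands:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tltr_element\t"
                     f"{int(round(1000 * c.ltr_identity))}\t+\n")
    print(f"[ltr_miner] {len(cands)} candidates -> {prefix}", file=sys.stderr)
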