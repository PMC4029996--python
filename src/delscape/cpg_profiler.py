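"""CpG-island detection and length-plasticity statistics for LTR sets.

Islands are called on a subgroup consensus by the classic windowed
criteria (window %GC and CpG observed/expected ratio both above
thresholds, merged runs at least ``min_len`` long).  Subgroup consensi are
classified into the three promoter-methylation patterns seen across the
Del lineage: A (no island), B (a 5'-half island only) and C (islands in
both halves).  The plasticity ratio — standard deviation of a region's
degapped length divided by its mean across the aligned LTRs — quantifies
how much more length-variable the island is than the rest of the LTR.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import DNA

PATTERN_A = "A"   # no CpG island
PATTERN_B = "B"   # 5' island only
PATTERN_C = "C"   # islands in both halves


@dataclass
class CpGIsland:
    start: int                  # 0-based half-open, on the consensus
    end: int
    mean_gc: float              # percent, averaged over qualifying windows
    mean_obs_exp: float
    half: str                   # five_prime | three_prime by midpoint

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlasticityReport:
    n: int
    island_mean: float
    island_sd: float
    island_ratio: float
    rest_mean: float
    rest_sd: float
    rest_ratio: float


def consensus(msa) -> str:
    """Majority-base consensus; columns with >50% gaps are removed.

    Ties go to the first base in A<C<G<T order.  Gap characters within a
    retained column are ignored for the majority count.
    """
    seqs = [str(s).upper() for s in msa]
    if not seqs:
        raise ValueError("empty alignment")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned to equal length")
    n = len(seqs)
    out = []
    for col in zip(*seqs):
        gaps = sum(1 for c in col if c in "-.")
        if gaps > n / 2:
            continue
        counts = {b: 0 for b in DNA}
        for c in col:
            if c in counts:
                counts[c] += 1
        best = max(counts.values())
        out.append(next(b for b in DNA if counts[b] == best) if best else "N")
    return "".join(out)


def window_stats(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """(%GC, Obs/Exp) for every window start; vectorised cumulative sums.

    Obs/Exp counts CG dinucleotides fully inside the window:
    (#CG * window) / (#C * #G), defined as 0 when #C or #G is 0.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(seq), dtype=np.int64)
    if len(seq) > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    cc, cg_, ccg = cum(is_c), cum(is_g), cum(is_cg)
    n = len(seq) - window + 1
    c = cc[window:window + n] - cc[:n]
    g = cg_[window:window + n] - cg_[:n]
    cg = ccg[window - 1:window - 1 + n] - ccg[:n]   # CG starts within window
    gc_pct = 100.0 * (c + g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c > 0) & (g > 0), cg * window / np.maximum(c * g, 1), 0.0)
    return gc_pct, oe


def find_cpg_islands(seq: str, window: int = 100, shift: int = 1,
                     min_len: int = 200, min_gc: float = 50.0,
                     min_oe: float = 0.6) -> list[CpGIsland]:
    """Windowed island calling: a position is island-like when covered by
    any window meeting both thresholds; maximal runs >= min_len become
    islands, with stats averaged over the qualifying windows overlapping
    each island."""
    seq = seq.upper()
    if len(seq) < window:
        warnings.warn("sequence shorter than the window; no islands called")
        return []
    gc_pct, oe = window_stats(seq, window)
    starts = np.arange(0, len(gc_pct), shift)
    qualifies = (gc_pct[starts] >= min_gc) & (oe[starts] >= min_oe)
    covered = np.zeros(len(seq), dtype=bool)
    for s in starts[qualifies]:
        covered[s:s + window] = True
    islands = []
    i = 0
    while i < len(seq):
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < len(seq) and covered[j]:
            j += 1
        if j - i >= min_len:
            overlapping = [s for s in starts[qualifies]
                           if s < j and s + window > i]
            islands.append(CpGIsland(
                start=i, end=j,
                mean_gc=float(np.mean(gc_pct[overlapping])),
                mean_obs_exp=float(np.mean(oe[overlapping])),
                half=("five_prime" if (i + j) / 2 < len(seq) / 2
                      else "three_prime"),
            ))
        i = j
    return islands


def conservation_track(msa, window: int = 10) -> np.ndarray:
    """Sliding mean of column identity (fraction matching the column
    majority base; gaps count as mismatches)."""
    seqs = [str(s).upper() for s in msa]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned to equal length")
    n = len(seqs)
    col_ident = []
    for col in zip(*seqs):
        counts = [sum(1 for c in col if c == b) for b in DNA]
        col_ident.append(max(counts) / n)
    col_ident = np.asarray(col_ident)
    if len(col_ident) < window:
        return col_ident
    kernel = np.ones(window) / window
    return np.convolve(col_ident, kernel, mode="valid")


def classify_pattern(islands: list[CpGIsland], consensus_length: int) -> str:
    """A = no island, B = 5'-half only, C = both halves."""
    halves = {isl.half for isl in islands}
    if not islands:
        return PATTERN_A
    if halves == {"five_prime"}:
        return PATTERN_B
    if halves == {"five_prime", "three_prime"}:
        return PATTERN_C
    warnings.warn("island(s) only in the 3' half; pattern 'other'")
    return "other"


def plasticity_ratio(msa, island_interval: tuple[int, int]
                     ) -> PlasticityReport:
    """SD/mean of degapped lengths for island columns vs the rest.

    ``island_interval`` is half-open on alignment columns.  Sample SD
    (n-1) throughout.
    """
    seqs = [str(s).upper() for s in msa]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned to equal length")
    width = len(seqs[0])
    a, b = island_interval
    if not (0 <= a < b <= width):
        raise ValueError("island interval empty or outside the alignment")
    island_lens, rest_lens = [], []
    for s in seqs:
        island = s[a:b]
        rest = s[:a] + s[b:]
        island_lens.append(sum(1 for c in island if c in DNA))
        rest_lens.append(sum(1 for c in rest if c in DNA))

    def summarize(lens):
        mean = float(np.mean(lens))
        sd = float(np.std(lens, ddof=1)) if len(lens) > 1 else 0.0
        return mean, sd, (sd / mean if mean else 0.0)

    im, isd, ir = summarize(island_lens)
    rm, rsd, rr = summarize(rest_lens)
    return PlasticityReport(len(seqs), im, isd, ir, rm, rsd, rr)


def split_by_identity(msa_ids, msa_seqs, min_identity: float = 0.8
                      ) -> list[list[str]]:
    """Single-linkage clusters of aligned LTRs at pairwise identity
    >= min_identity (matches / columns where both have a base); used to
    split heterogeneous subgroups before consensus building."""
    seqs = [str(s).upper() for s in msa_seqs]
    n = len(seqs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            both = [(a, b) for a, b in zip(seqs[i], seqs[j])
                    if a in DNA and b in DNA]
            if not both:
                continue
            ident = sum(a == b for a, b in both) / len(both)
            if ident >= min_identity:
                parent[find(i)] = find(j)
    clusters: dict[int, list[str]] = {}
    for i, taxon in enumerate(msa_ids):
        clusters.setdefault(find(i), []).append(taxon)
    return sorted(clusters.values(), key=lambda c: c[0])


def islands_table(islands: list[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start": isl.start, "end": isl.end, "length": isl.length,
        "mean_gc": round(isl.mean_gc, 2),
        "mean_obs_exp": round(isl.mean_obs_exp, 3), "half": isl.half,
    } for isl in islands], columns=["start", "end", "length", "mean_gc",
                                    "mean_obs_exp", "half"])


def write_report(islands, pattern: str, report: PlasticityReport | None,
                 prefix: str | Path) -> None:
    prefix = Path(prefix)
    islands_table(islands).to_csv(f"{prefix}.islands.tsv", sep="\t",
                                  index=False)
    with open(f"{prefix}.islands.bed", "w") as fh:
        for isl in islands:
            fh.write(f"consensus\t{isl.start}\t{isl.end}\tcpg_island\t0\t+\n")
    rows = [{"pattern": pattern}]
    if report is not None:
        rows[0].update({
            "n": report.n,
            "island_mean_len": round(report.island_mean, 2),
            "island_sd": round(report.island_sd, 2),
            "island_plasticity": round(report.island_ratio, 4),
            "rest_mean_len": round(report.rest_mean, 2),
            "rest_sd": round(report.rest_sd, 2),
            "rest_plasticity": round(report.rest_ratio, 4),
        })
    pd.DataFrame(rows).to_csv(f"{prefix}.summary.tsv", sep="\t", index=False)
    print(f"[cpg_profiler] pattern {pattern}, {len(islands)} island(s)",
          file=sys.stderr)
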