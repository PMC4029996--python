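"""Chromosome-scale exact-match scanning of a short att motif.

A 10-bp attachment-site motif is searched verbatim on both strands
(overlapping occurrences included), per-chromosome counts are normalised
to copies per 5 Mb, features are binned into 5-Mb windows for positional
tracks, and hits are validated by asking whether the 3-kb region
downstream of the motif (in the hit's own orientation — the LTR body lies
3' of the U3 att) aligns to a known LTR library at an identity/coverage
threshold.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from ._seq import DNA, revcomp

BIN_5MB = 5_000_000


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    position: int       # leftmost base of the match, plus-strand coords
    strand: str         # '+' or '-'


def scan_motif(genome: dict[str, str], motif: str,
               count_both_strands: bool = True) -> list[MotifHit]:
    """All exact occurrences of the motif, both strands, overlaps included.

    A minus-strand hit is an occurrence of the reverse complement on the
    plus strand.  A palindromic-context site therefore yields two hits
    unless ``count_both_strands`` is False, in which case coincident
    plus/minus hits of identical span are deduplicated to the plus strand.
    """
    motif = motif.upper()
    if any(b not in DNA for b in motif):
        raise ValueError("motif must contain only A, C, G, T")
    rc = revcomp(motif)
    hits: list[MotifHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        plus = _find_all(seq, motif)
        minus = _find_all(seq, rc)
        for p in plus:
            hits.append(MotifHit(chrom, p, "+"))
        plus_set = set(plus)
        for p in minus:
            if not count_both_strands and p in plus_set:
                continue
            hits.append(MotifHit(chrom, p, "-"))
    hits.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return hits


def _find_all(seq: str, pattern: str) -> list[int]:
    out, i = [], seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)   # overlapping occurrences included
    return out


def density(hits: list[MotifHit] | list[tuple], chrom_lengths: dict[str, int]
            ) -> pd.DataFrame:
    """Copies per 5 Mb per chromosome: count / length x 5e6.

    The returned frame carries one row per chromosome plus attrs
    ``mean`` and ``sd`` (sample SD across chromosomes).
    """
    counts = {name: 0 for name in chrom_lengths}
    for h in hits:
        chrom = h.chrom if isinstance(h, MotifHit) else h[0]
        if chrom not in counts:
            raise KeyError(f"hit on {chrom} but no length entry")
        counts[chrom] += 1
    rows = []
    for name in sorted(chrom_lengths):
        length = chrom_lengths[name]
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        rows.append({"chrom": name, "count": counts[name], "length": length,
                     "density_per_5mb": counts[name] / length * BIN_5MB})
    table = pd.DataFrame(rows)
    dens = table["density_per_5mb"]
    table.attrs["mean"] = float(dens.mean())
    table.attrs["sd"] = float(dens.std(ddof=1)) if len(dens) > 1 else 0.0
    return table


def window_track(features, chrom_lengths: dict[str, int],
                 bin_size: int = BIN_5MB) -> pd.DataFrame:
    """Counts per half-open bin [k*bin, (k+1)*bin) per chromosome.

    ``features`` are MotifHits or (chrom, start) pairs; a feature belongs
    to the bin containing its start.  The last partial bin is reported
    with its true width.
    """
    rows = []
    starts: dict[str, list[int]] = {name: [] for name in chrom_lengths}
    for f in features:
        chrom, start = (f.chrom, f.position) if isinstance(f, MotifHit) \
            else (f[0], f[1])
        if chrom not in starts:
            raise KeyError(f"feature on {chrom} but no length entry")
        starts[chrom].append(start)
    for name in sorted(chrom_lengths):
        length = chrom_lengths[name]
        n_bins = max(1, -(-length // bin_size))
        counts = np.zeros(n_bins, dtype=np.int64)
        for s in starts[name]:
            counts[min(s // bin_size, n_bins - 1)] += 1
        for k in range(n_bins):
            lo = k * bin_size
            hi = min(length, lo + bin_size)
            rows.append({"chrom": name, "bin_start": lo, "bin_end": hi,
                         "bin_width": hi - lo, "count": int(counts[k])})
    return pd.DataFrame(rows)


def expected_by_chance(motif_len: int = 10, bin_size: int = BIN_5MB,
                       both_strands: bool = True) -> float:
    """Expected hits per bin under a uniform base model: bin/4^len per
    strand, doubled when both strands are scanned."""
    per_strand = bin_size / (4 ** motif_len)
    return 2.0 * per_strand if both_strands else per_strand


def validate_hits(genome: dict[str, str], hits: list[MotifHit],
                  ltr_library: dict[str, str], flank: int = 3000,
                  min_identity: float = 0.80, min_coverage: int = 100,
                  motif_len: int = 10) -> float | None:
    """Percent of hits whose downstream 3-kb flank matches a library LTR.

    Downstream is read in the hit's orientation: 3'-ward on the plus
    strand for '+' hits, 5'-ward (then reverse-complemented) for '-'
    hits.  A hit is associated when any library LTR prefix aligns inside
    the flank (edlib infix alignment) at >= min_identity over
    >= min_coverage bases.  Returns None (undefined) for an empty hit
    list, not 0%.
    """
    if not ltr_library:
        raise ValueError("empty LTR library")
    if not hits:
        return None
    queries = []
    for name in sorted(ltr_library):
        ltr = ltr_library[name].upper()
        q = ltr[:flank]
        if len(q) >= min_coverage:
            queries.append(q)
    if not queries:
        raise ValueError("no library LTR reaches min_coverage")
    associated = 0
    for h in hits:
        seq = genome[h.chrom].upper()
        if h.strand == "+":
            region = seq[h.position:h.position + flank]
        else:
            region = revcomp(seq[max(0, h.position + motif_len - flank):
                                 h.position + motif_len])
        if len(region) < flank:
            print(f"[genome_scanner] flank truncated at {h.chrom}:"
                  f"{h.position}", file=sys.stderr)
        if len(region) < min_coverage:
            continue
        for q in queries:
            qq = q[:len(region)]
            if len(qq) < min_coverage:
                continue
            res = edlib.align(qq, region, mode="HW", task="distance")
            if 1.0 - res["editDistance"] / len(qq) >= min_identity:
                associated += 1
                break
    return 100.0 * associated / len(hits)


def write_hits_bed(hits: list[MotifHit], motif: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.position}\t{h.position + len(motif)}\t"
                     f"{motif}\t0\t{h.strand}\n")
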