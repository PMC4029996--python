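"""Lineage assignment by scoring six-frame translations against
reverse-transcriptase domain profiles.

Each lineage (Del, Reina, CRM, Galadriel, ...) is represented by a
per-column amino-acid log-odds matrix (a PSSM) built from a reference RT
alignment with pseudocounts:

    log_odds[col, aa] = log2( ((count + pc * bg_aa) / (n_col + pc)) / bg_aa )

An element is conceptually translated in all six frames and the best
ungapped window score over all frames and profiles decides the lineage;
the decision threshold is a bit score, by default calibrated on shuffled-
sequence nulls (max null score + margin).  This is a transparent
best-match scanner, not a profile HMM: there are no insert/delete states
and no E-value statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._seq import revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
UNIFORM_BACKGROUND = {a: 1.0 / 20.0 for a in AMINO_ACIDS}
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class LineageProfile:
    lineage: str
    log_odds: np.ndarray            # (columns, 20)
    background: np.ndarray          # (20,)

    @property
    def n_columns(self) -> int:
        return self.log_odds.shape[0]

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class ClassificationResult:
    element_id: str
    lineage: str
    bit_score: float
    frame: int
    offset: int                     # aa offset of the best window
    passed: bool


def build_profile(reference_msa, lineage: str = "profile",
                  pseudocount: float = 1.0,
                  background: dict[str, float] | None = None,
                  max_gap_fraction: float = 0.5) -> LineageProfile:
    """Log-odds profile from an aligned amino-acid reference set.

    Columns with more than ``max_gap_fraction`` gaps are dropped; within a
    column, gap characters do not count toward n.
    """
    seqs = [str(s).upper() for s in reference_msa]
    if len(seqs) < 2:
        raise ValueError("need at least 2 reference sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("reference sequences are not aligned")
    bg_map = background or UNIFORM_BACKGROUND
    bg = np.array([bg_map[a] for a in AMINO_ACIDS])
    bg = bg / bg.sum()
    columns = []
    for col in zip(*seqs):
        gaps = sum(1 for c in col if c in "-.")
        if gaps > max_gap_fraction * len(col):
            continue
        counts = np.zeros(20)
        for c in col:
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
        n = counts.sum()
        probs = (counts + pseudocount * bg) / (n + pseudocount)
        columns.append(np.log2(probs / bg))
    if not columns:
        raise ValueError("no usable columns in the reference alignment")
    return LineageProfile(lineage, np.vstack(columns), bg)


def _translate_frames(seq: str) -> dict[int, str]:
    seq = seq.upper().replace("U", "T")
    out = {}
    for frame in FRAMES:
        s = seq if frame > 0 else revcomp(seq)
        off = abs(frame) - 1
        trimmed = s[off:off + 3 * ((len(s) - off) // 3)]
        out[frame] = str(Seq(trimmed).translate())
    return out


def score_translation(protein: str, profile: LineageProfile
                      ) -> tuple[float, int]:
    """Best ungapped window score of a translation against one profile.

    Internal stops and unknown residues score the worst value of the
    column (the profile keeps scanning across them).
    """
    w = profile.n_columns
    if len(protein) < w:
        return -np.inf, 0
    worst = profile.log_odds.min(axis=1)
    scores = np.empty((len(protein), w))
    for col in range(w):
        scores[:, col] = worst[col]
    for pos, aa in enumerate(protein):
        if aa in AA_INDEX:
            scores[pos, :] = profile.log_odds[:, AA_INDEX[aa]]
    best, best_off = -np.inf, 0
    for off in range(len(protein) - w + 1):
        s = float(np.trace(scores[off:off + w, :]))
        if s > best:
            best, best_off = s, off
    return best, best_off


def classify(element_seq: str, profiles: list[LineageProfile],
             threshold_bits: float = 0.0, element_id: str = "element"
             ) -> ClassificationResult:
    """Best profile over all six frames; ties break on lineage name."""
    if not profiles:
        raise ValueError("no profiles supplied")
    if not any(len(element_seq) >= 3 * p.n_columns for p in profiles):
        raise ValueError("element shorter than every profile")
    translations = _translate_frames(element_seq)
    best = None
    for profile in sorted(profiles, key=lambda p: p.lineage):
        for frame in FRAMES:
            score, off = score_translation(translations[frame], profile)
            key = (-score, profile.lineage, abs(frame), frame < 0)
            if best is None or key < best[0]:
                best = (key, profile.lineage, score, frame, off)
    _, lineage, score, frame, off = best
    return ClassificationResult(element_id, lineage, score, frame, off,
                                passed=score >= threshold_bits)


def calibrate_threshold(profiles: list[LineageProfile], length: int = 3000,
                        n_shuffles: int = 50, margin_bits: float = 10.0,
                        seed: int = 0) -> float:
    """Bit threshold = max best-score over random nulls + margin."""
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_shuffles):
        null = "".join(rng.choice(list("ACGT"), size=length))
        res = classify(null, profiles, threshold_bits=np.inf)
        best = max(best, res.bit_score)
    return best + margin_bits


def results_table(results: list[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "element_id": r.element_id, "lineage": r.lineage,
        "bit_score": round(r.bit_score, 2), "frame": r.frame,
        "offset": r.offset, "passed": r.passed,
    } for r in results], columns=["element_id", "lineage", "bit_score",
                                  "frame", "offset", "passed"])
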