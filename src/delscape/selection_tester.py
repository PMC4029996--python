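"""Codon-level selection analysis: alignment preparation, Wright's
effective number of codons, and site models M0/M1a/M2a with likelihood-
ratio tests.

The site models share the reversible sense-codon process of
:mod:`delscape.codon_model` (single-nucleotide steps, transition/
transversion ratio kappa, nonsynonymous factor omega, F3x4 equilibrium
frequencies, mean rate scaled to one).  M0 gives every site one omega;
M1a mixes a purifying class (0 <= omega0 < 1, proportion p0) with a
neutral class (omega = 1); M2a adds a positively selected class
(omega2 > 1).  Site likelihoods are computed by Felsenstein pruning over
a fixed input topology with per-pattern rescaling; only a global
branch-length scale is re-optimised together with the substitution
parameters (bounded quasi-Newton from a fixed grid of starting points,
screened by a single likelihood evaluation each).  Nested fits are
compared with chi-squared likelihood-ratio tests (df 1 for M0 vs M1a,
df 2 for M1a vs M2a).
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._tree import SimpleTree
from .codon_model import (CODON_AA, CODON_INDEX, CodonProcess, GENETIC_CODE,
                          N_CODONS, SENSE_CODONS, f3x4_frequencies)

MODELS = ("M0", "M1a", "M2a")
MAX_INDEL_NT = 15           # contiguous indel > 5 amino acids drops the row


@dataclass
class CodonAlignment:
    ids: list[str]
    codons: np.ndarray          # (n_seqs, n_codons) indices into SENSE_CODONS
    excluded_sequences: list[str] = field(default_factory=list)
    excluded_columns: list[int] = field(default_factory=list)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def sequences(self) -> dict[str, str]:
        return {t: "".join(SENSE_CODONS[c] for c in row)
                for t, row in zip(self.ids, self.codons)}


@dataclass
class CodonModelFit:
    model: str
    kappa: float
    omegas: tuple[float, ...]
    proportions: tuple[float, ...]
    branch_scale: float
    lnl: float
    pi: np.ndarray
    n_parameters: int
    n_sequences: int
    n_codons: int


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    two_delta_l: float
    df: int
    p_value: float
    significant_001: bool


def _longest_gap_run(seq: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c in "-." else 0
        best = max(best, run)
    return best


def prepare_codon_alignment(msa: dict[str, str]) -> CodonAlignment:
    """In-frame alignment to gap-free sense codons.

    Sequences with a contiguous indel longer than five amino acids
    (15 nt) are dropped first; then every codon column containing a gap,
    stop or ambiguous codon in any retained sequence is excluded.
    """
    ids = list(msa)
    if not ids:
        raise ValueError("empty alignment")
    width = len(msa[ids[0]])
    if width % 3:
        raise ValueError("alignment width must be divisible by 3")
    if any(len(msa[t]) != width for t in ids):
        raise ValueError("sequences are not aligned to equal length")
    kept, dropped = [], []
    for t in ids:
        (dropped if _longest_gap_run(msa[t]) > MAX_INDEL_NT else kept).append(t)
    if len(kept) < 3:
        raise ValueError("fewer than 3 sequences after indel filtering")
    excluded_cols = []
    columns = []
    for c in range(width // 3):
        codons = [msa[t][3 * c:3 * c + 3].upper() for t in kept]
        if all(cd in CODON_INDEX for cd in codons):
            columns.append([CODON_INDEX[cd] for cd in codons])
        else:
            excluded_cols.append(c)
    if not columns:
        raise ValueError("no usable codon columns")
    codons = np.array(columns, dtype=np.int64).T
    return CodonAlignment(kept, codons, dropped, excluded_cols)


# ---------------------------------------------------------------------------
# effective number of codons (Wright)

_DEGENERACY_CLASSES: dict[int, list[list[str]]] = {}
for _aa in set(GENETIC_CODE.values()) - {"*"}:
    _syn = [c for c, a in GENETIC_CODE.items() if a == _aa]
    _DEGENERACY_CLASSES.setdefault(len(_syn), []).append(sorted(_syn))
# standard code: 2 singletons (M, W), 9 two-fold, 1 three-fold (I),
# 5 four-fold, 3 six-fold (L, S, R)
_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}


def effective_number_of_codons(usage: dict[str, float]) -> float:
    """Wright's Nc from codon usage (counts or frequencies).

    Per amino acid, homozygosity F = sum p_i^2 over its synonymous codons
    (frequency-based); Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the
    mean F over the k-fold degeneracy class, capped at 61.  An entirely
    unobserved amino acid is skipped when averaging its class; an
    entirely unobserved class is imputed as 1/k (uniform usage) with a
    warning.
    """
    usage = {c.upper().replace("U", "T"): v for c, v in usage.items()}
    class_f: dict[int, float] = {}
    for fold, amino_acids in _DEGENERACY_CLASSES.items():
        if fold == 1:
            continue
        fs = []
        for codons in amino_acids:
            total = sum(usage.get(c, 0.0) for c in codons)
            if total <= 0:
                continue
            fs.append(sum((usage.get(c, 0.0) / total) ** 2 for c in codons))
        if fs:
            class_f[fold] = float(np.mean(fs))
        else:
            print(f"[selection_tester] no usage in the {fold}-fold class; "
                  f"imputing uniform", file=sys.stderr)
            class_f[fold] = 1.0 / fold
    nc = 2.0 + sum(w / class_f[fold] for fold, w in _CLASS_WEIGHT.items())
    return min(nc, 61.0)


def nc_report(aln: CodonAlignment) -> pd.DataFrame:
    """Per-sequence Nc plus the mean +/- SD row."""
    rows = []
    for t, row in zip(aln.ids, aln.codons):
        usage: dict[str, float] = {}
        for c in row:
            usage[SENSE_CODONS[c]] = usage.get(SENSE_CODONS[c], 0.0) + 1.0
        rows.append({"sequence": t,
                     "nc": effective_number_of_codons(usage)})
    table = pd.DataFrame(rows)
    table.attrs["mean"] = float(table["nc"].mean())
    table.attrs["sd"] = float(table["nc"].std(ddof=1)) if len(table) > 1 \
        else 0.0
    return table


# ---------------------------------------------------------------------------
# likelihood machinery

class _Pruner:
    """Felsenstein pruning over compressed site patterns with rescaling."""

    def __init__(self, aln: CodonAlignment, tree: SimpleTree):
        labels = set(aln.ids)
        if set(tree.leaf_labels) != labels:
            raise ValueError("tree taxa do not match alignment ids")
        self.tree = tree
        patterns, self.weights = np.unique(aln.codons, axis=1,
                                           return_counts=True)
        self.patterns = patterns            # (n_seqs, n_patterns)
        self.row_of = {t: i for i, t in enumerate(aln.ids)}
        self.n_patterns = patterns.shape[1]

    def site_loglikes(self, process: CodonProcess, scale: float
                      ) -> np.ndarray:
        """Per-pattern log-likelihood for one omega class."""
        tree = self.tree
        partials: dict[int, np.ndarray] = {}
        scalers = np.zeros(self.n_patterns)
        for idx in tree.postorder:
            node = tree.nodes[idx]
            if not node.children:
                continue
            part = np.ones((N_CODONS, self.n_patterns))
            for child_idx in node.children:
                child = tree.nodes[child_idx]
                p = process.transition_matrix(child.edge_length * scale)
                if not child.children:
                    codes = self.patterns[self.row_of[child.label]]
                    part *= p[:, codes]
                else:
                    part *= p @ partials[child_idx]
            peak = part.max(axis=0)
            peak[peak == 0] = 1.0
            part /= peak
            scalers += np.log(peak)
            partials[idx] = part
        root = partials[tree.postorder[-1]]
        like = process.pi @ root
        return np.log(np.maximum(like, 1e-300)) + scalers


def _mixture_lnl(pruner: _Pruner, pi: np.ndarray, kappa: float,
                 omegas, proportions, scale: float) -> float:
    logs = np.stack([
        pruner.site_loglikes(CodonProcess(kappa, w, pi), scale)
        for w in omegas
    ])
    logp = np.log(np.maximum(np.asarray(proportions)[:, None], 1e-300))
    site = logsumexp_rows(logs + logp)
    return float((site * pruner.weights).sum())


def logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


def _unpack(model: str, x: np.ndarray):
    sigmoid = lambda v: 1.0 / (1.0 + np.exp(-v))
    kappa = float(np.exp(x[0]))
    scale = float(np.exp(x[-1]))
    if model == "M0":
        return kappa, (float(np.exp(x[1])),), (1.0,), scale
    if model == "M1a":
        p0 = float(sigmoid(x[1]))
        w0 = float(sigmoid(x[2]))
        return kappa, (w0, 1.0), (p0, 1.0 - p0), scale
    p0 = float(sigmoid(x[1]))
    p1 = float((1.0 - p0) * sigmoid(x[2]))
    w0 = float(sigmoid(x[3]))
    w2 = float(1.0 + np.exp(x[4]))
    return kappa, (w0, 1.0, w2), (p0, p1, 1.0 - p0 - p1), scale


def _starting_points(model: str, warm: CodonModelFit | None) -> list[np.ndarray]:
    logit = lambda p: np.log(p / (1.0 - p))
    kappas = (1.0, 2.0, 5.0)
    starts = []
    if model == "M0":
        for k in kappas:
            for w in (0.1, 0.5, 1.5):
                starts.append(np.array([np.log(k), np.log(w), 0.0]))
    elif model == "M1a":
        for k in kappas:
            for w0 in (0.1, 0.5):
                for p0 in (0.5, 0.9):
                    starts.append(np.array([np.log(k), logit(p0),
                                            logit(w0), 0.0]))
        if warm is not None and warm.model == "M0":
            w0 = min(max(warm.omegas[0], 1e-3), 0.95)
            starts.insert(0, np.array([np.log(warm.kappa), logit(0.8),
                                       logit(w0),
                                       np.log(warm.branch_scale)]))
    else:  # M2a
        for k in kappas:
            for w2 in (1.5, 3.0):
                starts.append(np.array([np.log(k), logit(0.7), logit(0.5),
                                        logit(0.1), np.log(w2 - 1.0), 0.0]))
        if warm is not None and warm.model == "M1a":
            w0 = min(max(warm.omegas[0], 1e-3), 0.95)
            p0 = min(max(warm.proportions[0], 0.05), 0.9)
            starts.insert(0, np.array([
                np.log(warm.kappa), logit(p0), logit(0.5), logit(w0),
                np.log(0.5), np.log(warm.branch_scale)]))
    return starts


def fit_site_model(aln: CodonAlignment, tree: str | SimpleTree,
                   model: str = "M0", pi: np.ndarray | None = None,
                   warm_start: CodonModelFit | None = None,
                   n_optimized_starts: int = 2) -> CodonModelFit:
    """Maximum-likelihood fit of one site model on a fixed topology.

    ``pi`` defaults to F3x4 frequencies computed from the alignment.  The
    fixed start grid is screened with one likelihood evaluation per
    start; full bounded quasi-Newton optimisation runs from the
    ``n_optimized_starts`` best (plus a warm start from the nested null
    fit when given).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if isinstance(tree, str):
        tree = SimpleTree.from_newick(tree, require_lengths=True)
    pruner = _Pruner(aln, tree)
    if pi is None:
        pi = f3x4_frequencies(aln.sequences().values())

    def negative_lnl(x: np.ndarray) -> float:
        kappa, omegas, props, scale = _unpack(model, x)
        if not np.isfinite(kappa) or kappa <= 0 or scale <= 0:
            return 1e12
        try:
            return -_mixture_lnl(pruner, pi, kappa, omegas, props, scale)
        except (ValueError, FloatingPointError):
            return 1e12

    starts = _starting_points(model, warm_start)
    screened = sorted(starts, key=negative_lnl)
    n_opt = max(1, min(n_optimized_starts, len(screened)))
    best = None
    for x0 in screened[:n_opt]:
        res = optimize.minimize(negative_lnl, x0, method="L-BFGS-B",
                                options={"maxiter": 400, "ftol": 1e-10,
                                         "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(f"optimizer failed for {model}")
    kappa, omegas, props, scale = _unpack(model, best.x)
    n_params = {"M0": 3, "M1a": 4, "M2a": 6}[model]
    return CodonModelFit(model, kappa, omegas, props, scale,
                         -float(best.fun), pi, n_params,
                         len(aln.ids), aln.n_codons)


_NESTED = {("M0", "M1a"): 1, ("M1a", "M2a"): 2}


def lrt(null: CodonModelFit, alt: CodonModelFit) -> LRTResult:
    """Chi-squared likelihood-ratio test of nested site models."""
    key = (null.model, alt.model)
    if key not in _NESTED:
        raise ValueError(f"{null.model} is not nested in {alt.model}")
    df = _NESTED[key]
    two_delta = max(0.0, 2.0 * (alt.lnl - null.lnl))
    p = float(stats.chi2.sf(two_delta, df))
    if alt.lnl < null.lnl - 1e-4:
        print(f"[selection_tester] alt lnl below null by "
              f"{null.lnl - alt.lnl:.3g}; treated as 2dl=0", file=sys.stderr)
    return LRTResult(null.model, alt.model, two_delta, df, p, p < 0.001)


def fit_table(fits: list[CodonModelFit], lrts: list[LRTResult],
              nc: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summary table: one row per model, selection-test shape."""
    lrt_by_alt = {r.alt_model: r for r in lrts}
    rows = []
    for f in fits:
        row = {
            "model": f.model, "n_sequences": f.n_sequences,
            "n_codons": f.n_codons, "kappa": round(f.kappa, 4),
            "lnl": round(f.lnl, 5), "branch_scale": round(f.branch_scale, 5),
        }
        for k, (w, p) in enumerate(zip(f.omegas, f.proportions)):
            row[f"omega{k}"] = round(w, 5)
            row[f"p{k}"] = round(p, 5)
        if nc is not None:
            row["nc_mean"] = round(nc.attrs["mean"], 2)
            row["nc_sd"] = round(nc.attrs["sd"], 2)
        r = lrt_by_alt.get(f.model)
        if r is not None:
            row["two_delta_l"] = round(r.two_delta_l, 5)
            row["df"] = r.df
            row["p_value"] = r.p_value
            row["significance"] = "**" if r.significant_001 else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(fits: list[CodonModelFit], path: str | Path) -> None:
    payload = [{
        "model": f.model, "kappa": f.kappa, "omegas": list(f.omegas),
        "proportions": list(f.proportions), "branch_scale": f.branch_scale,
        "lnl": f.lnl, "n_parameters": f.n_parameters,
        "n_sequences": f.n_sequences, "n_codons": f.n_codons,
    } for f in fits]
    Path(path).write_text(json.dumps(payload, indent=2))
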