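"""Synthetic plant chromosomes with planted Del-like LTR retrotransposons.

The generator plants structurally faithful elements in iid background
sequence: paired LTRs derived from one ancestral LTR and mutated
independently (so the expected LTR–LTR identity equals the configured
divergence), TG...CA termini, a 10-bp U3 attachment motif opening the LTR
and an 11-bp U5 attachment motif closing it, 4–6 bp target-site
duplications, optional CpG islands of controllable length variance in
either LTR half, plus truncated copies, solo LTRs and nested insertions.
Every planted feature is reported in a machine-readable truth table so the
mining, att-calling, CpG and scanning stages can be scored exactly.

It also simulates in-frame codon alignments under the sense-codon
substitution process used by the selection tester, for parameter-recovery
experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import DNA, gc_fraction, random_dna
from ._tree import SimpleTree
from .codon_model import CodonProcess, SENSE_CODONS, uniform_frequencies

U5_TYPE_A_TRIPLET = "GGG"
U5_TYPE_B_TRIPLET = "TTC"


class SizingError(ValueError):
    """Planted elements cannot fit in the configured chromosomes."""


class InfeasibleIslandError(ValueError):
    """CpG-island spec targets cannot be reached for any sequence."""


@dataclass(frozen=True)
class CpGIslandSpec:
    """Where and how strong a planted CpG island is.

    offset_frac places the island start as a fraction of LTR length
    (0 = 5' terminus); gc_percent and obs_exp are minimum targets the
    planted block will meet or exceed.
    """

    offset_frac: float
    mean_len: int = 300
    sd_len: float = 0.0
    gc_percent: float = 60.0
    obs_exp: float = 0.75

    def __post_init__(self):
        if not 0.0 <= self.offset_frac <= 1.0:
            raise ValueError("offset_frac must be in [0,1]")
        if self.mean_len <= 0 or self.sd_len < 0:
            raise ValueError("island length parameters must be positive")
        gc = self.gc_percent / 100.0
        if not 0.0 < gc <= 0.95:
            raise InfeasibleIslandError("target %GC must be in (0, 95]")
        # max Obs/Exp for a block with #C ~ #G ~ gc*L/2 is about 2/gc
        if self.obs_exp > 2.0 / gc:
            raise InfeasibleIslandError(
                f"Obs/Exp target {self.obs_exp} unreachable at {self.gc_percent}%GC"
            )


@dataclass(frozen=True)
class ElementTemplate:
    """Structural blueprint of one Del-like family."""

    name: str = "delA"
    ltr_length_mean: float = 2000.0
    ltr_length_sd: float = 100.0
    u3_att: str = "TGTAACACCC"
    u5_att: str = "TGGGTGAACCA"
    cpg5: CpGIslandSpec | None = None
    cpg3: CpGIslandSpec | None = None
    internal_length: int = 6000
    tsd_length: int = 5

    def __post_init__(self):
        if len(self.u3_att) != 10 or not self.u3_att.startswith("TG"):
            raise ValueError("u3_att must be 10 bp and start with TG")
        if len(self.u5_att) != 11 or not self.u5_att.endswith("CA"):
            raise ValueError("u5_att must be 11 bp and end with CA")
        if not 4 <= self.tsd_length <= 6:
            raise ValueError("tsd_length must be in [4,6]")
        if self.ltr_length_mean <= 0 or self.internal_length <= 0:
            raise ValueError("lengths must be positive")

    @property
    def u5_type(self) -> str:
        # positions -10,-9,-8 of the 11-mer ending the LTR (-1 = last base)
        triplet = self.u5_att[1:4]
        if triplet == U5_TYPE_A_TRIPLET:
            return "A"
        if triplet == U5_TYPE_B_TRIPLET:
            return "B"
        return "other"


def type_b_template(**kwargs) -> ElementTemplate:
    """Convenience template carrying the type-B (TTC) U5 att."""
    kwargs.setdefault("name", "delB")
    kwargs.setdefault("u5_att", "TTTCTGAACCA")
    return ElementTemplate(**kwargs)


@dataclass(frozen=True)
class SimConfig:
    chromosome_lengths: tuple[int, ...] = (1_000_000,)
    background_gc: float = 0.44
    templates: tuple[ElementTemplate, ...] = (ElementTemplate(),)
    copy_counts: tuple[int, ...] = (20,)
    truncated_fraction: float = 0.0
    solo_fraction: float = 0.0
    nesting_rate: float = 0.0
    ltr_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for frac in (self.truncated_fraction, self.solo_fraction,
                     self.nesting_rate, self.background_gc):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0,1]")
        if not 0.0 <= self.ltr_divergence < 1.0:
            raise ValueError("ltr_divergence must be in [0,1)")
        if len(self.templates) != len(self.copy_counts):
            raise ValueError("copy_counts must parallel templates")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")


TRUTH_COLUMNS = [
    "chrom", "start", "end", "status", "ltr5_start", "ltr5_end",
    "ltr3_start", "ltr3_end", "tsd", "template",
]


def _block_obs_exp(seq: str) -> float:
    c, g = seq.count("C"), seq.count("G")
    if c == 0 or g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (c * g)


def plant_cpg_island(ltr_seq: str, spec: CpGIslandSpec | None,
                     rng: np.random.Generator) -> str:
    """Overwrite a segment of the LTR with a block meeting the island spec.

    The block is drawn iid at the target G+C and then greedily enriched
    (A/T -> C/G conversions, then CG dinucleotide conversions) until both
    the %GC and Obs/Exp targets are met, so a windowed island caller is
    guaranteed to see a qualifying region.  Terminal att motifs (first 10,
    last 11 bases) are never overwritten.
    """
    if spec is None:
        return ltr_seq
    length = int(round(rng.normal(spec.mean_len, spec.sd_len))) if spec.sd_len \
        else int(spec.mean_len)
    length = max(length, 20)
    if length >= len(ltr_seq) - 21:
        raise InfeasibleIslandError("island does not fit inside the LTR")
    gc_target = spec.gc_percent / 100.0
    # enforce the targets on every ~100-bp chunk, so sliding windows of
    # comparable size see a qualifying signal throughout the block
    chunks = []
    n_chunks = max(1, length // 100)
    bounds = np.linspace(0, length, n_chunks + 1).astype(int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = list(random_dna(rng, int(b - a), gc=gc_target))
        budget = 40 * len(chunk)
        while budget:
            s = "".join(chunk)
            gc_ok = gc_fraction(s) * 100.0 >= spec.gc_percent
            oe_ok = _block_obs_exp(s) >= spec.obs_exp
            if gc_ok and oe_ok:
                break
            if not gc_ok:
                at_pos = [i for i, x in enumerate(chunk) if x in "AT"]
                if not at_pos:
                    raise InfeasibleIslandError("cannot raise %GC further")
                chunk[int(rng.choice(at_pos))] = str(rng.choice(["C", "G"]))
            else:
                cand = [i for i in range(len(chunk) - 1)
                        if chunk[i] + chunk[i + 1] != "CG"]
                if not cand:
                    raise InfeasibleIslandError("cannot raise Obs/Exp further")
                i = int(rng.choice(cand))
                chunk[i], chunk[i + 1] = "C", "G"
            budget -= 1
        else:
            raise InfeasibleIslandError("island targets not reached")
        chunks.append("".join(chunk))
    block = list("".join(chunks))
    start = int(round(spec.offset_frac * len(ltr_seq)))
    start = min(max(start, 10), len(ltr_seq) - 11 - length)
    return ltr_seq[:start] + "".join(block) + ltr_seq[start + length:]


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: np.ndarray | None = None) -> str:
    """Substitute bases iid at the given per-site rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    if protected is not None:
        hit &= ~protected
    for i in np.flatnonzero(hit):
        choices = [b for b in DNA if b != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def make_ltr_pair(template: ElementTemplate, divergence: float,
                  rng: np.random.Generator) -> tuple[str, str]:
    """One ancestral LTR, mutated into two copies at half the divergence each.

    Terminal att motifs are protected so planted termini stay verbatim.
    """
    length = int(round(rng.normal(template.ltr_length_mean,
                                  template.ltr_length_sd)))
    length = max(length, 200)
    ancestor = (template.u3_att
                + random_dna(rng, length - 21, gc=0.45)
                + template.u5_att)
    ancestor = plant_cpg_island(ancestor, template.cpg5, rng)
    ancestor = plant_cpg_island(ancestor, template.cpg3, rng)
    protected = np.zeros(length, dtype=bool)
    protected[:10] = True
    protected[-11:] = True
    half = divergence / 2.0
    return (_mutate(ancestor, half, rng, protected),
            _mutate(ancestor, half, rng, protected))


@dataclass
class _Insert:
    """A planned insertion: sequence plus feature offsets relative to it."""
    seq: str
    status: str
    tsd: str
    template: str
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    children: list["_Insert"] = dataclasses.field(default_factory=list)
    child_offsets: list[int] = dataclasses.field(default_factory=list)


def _build_copy(template: ElementTemplate, status: str, divergence: float,
                rng: np.random.Generator) -> _Insert:
    ltr5, ltr3 = make_ltr_pair(template, divergence, rng)
    tsd = random_dna(rng, template.tsd_length)
    internal = random_dna(rng, template.internal_length, gc=0.45)
    if status == "solo_ltr":
        return _Insert(ltr5, status, tsd, template.name,
                       (0, len(ltr5)), None)
    full = ltr5 + internal + ltr3
    ins = _Insert(full, status, tsd, template.name,
                  (0, len(ltr5)), (len(full) - len(ltr3), len(full)))
    if status == "truncated":
        cut = int(rng.integers(20, len(ltr5)))  # removes the 5' LTR start
        ins = _Insert(full[cut:], status, "", template.name,
                      None, (len(full) - len(ltr3) - cut, len(full) - cut))
    return ins


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate chromosomes and the truth table of every planted feature.

    Returns ``(chromosomes, truth)`` where chromosomes maps name to
    sequence and truth is a DataFrame with 0-based half-open coordinates
    (element interval excludes the flanking TSD copies).
    """
    rng = np.random.default_rng(config.seed)
    inserts: list[_Insert] = []
    for template, n_copies in zip(config.templates, config.copy_counts):
        for _ in range(int(n_copies)):
            u = rng.random()
            if u < config.truncated_fraction:
                status = "truncated"
            elif u < config.truncated_fraction + config.solo_fraction:
                status = "solo_ltr"
            else:
                status = "full_length"
            inserts.append(_build_copy(template, status,
                                       config.ltr_divergence, rng))

    # nest some full-length copies inside earlier full-length internal regions
    top_level: list[_Insert] = []
    for ins in inserts:
        hosts = [h for h in top_level
                 if h.status in ("full_length", "nested_host")]
        if (ins.status == "full_length" and hosts
                and rng.random() < config.nesting_rate):
            host = hosts[int(rng.integers(len(hosts)))]
            # insertion expands the host, so any internal position works
            lo = host.ltr5[1] + 50
            hi = host.ltr3[0] - 50
            if hi > lo:
                pos = int(rng.integers(lo, hi))
                piece = ins.tsd + ins.seq + ins.tsd
                host.seq = host.seq[:pos] + piece + host.seq[pos:]
                shift = len(piece)
                host.ltr3 = (host.ltr3[0] + shift, host.ltr3[1] + shift)
                for k in range(len(host.child_offsets)):
                    if host.child_offsets[k] >= pos:
                        host.child_offsets[k] += shift
                host.children.append(ins)
                host.child_offsets.append(pos + len(ins.tsd))
                host.status = "nested_host"
                continue
        top_level.append(ins)

    # place top-level inserts on chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chromosome_lengths))]
    chroms = {name: np.frombuffer(
                  random_dna(rng, length, gc=config.background_gc).encode(),
                  dtype=np.uint8).copy()
              for name, length in zip(chrom_names, config.chromosome_lengths)}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}
    rows: list[dict] = []
    for ins in top_level:
        piece = (ins.tsd + ins.seq + ins.tsd) if ins.tsd else ins.seq
        fits = [n for n, length in zip(chrom_names, config.chromosome_lengths)
                if len(piece) + 200 < length]
        if not fits:
            raise SizingError(
                f"insert of {len(piece)} bp exceeds every chromosome")
        placed = False
        for _ in range(2000):
            name = fits[int(rng.integers(len(fits)))]
            limit = len(chroms[name]) - len(piece) - 100
            start = int(rng.integers(100, limit))
            span = (start - 100, start + len(piece) + 100)
            if all(span[1] <= a or span[0] >= b for a, b in occupied[name]):
                occupied[name].append(span)
                chroms[name][start:start + len(piece)] = np.frombuffer(
                    piece.encode(), dtype=np.uint8)
                placed = True
                break
        if not placed:
            raise SizingError("could not place all inserts without overlap")
        offset = start + len(ins.tsd)
        rows.extend(_truth_rows(ins, name, offset))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if len(truth):
        truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    return ({n: c.tobytes().decode("ascii") for n, c in chroms.items()}, truth)


def _truth_rows(ins: _Insert, chrom: str, offset: int) -> list[dict]:
    def interval(iv):
        return (offset + iv[0], offset + iv[1]) if iv else (pd.NA, pd.NA)

    l5, l3 = interval(ins.ltr5), interval(ins.ltr3)
    rows = [{
        "chrom": chrom, "start": offset, "end": offset + len(ins.seq),
        "status": ins.status, "ltr5_start": l5[0], "ltr5_end": l5[1],
        "ltr3_start": l3[0], "ltr3_end": l3[1], "tsd": ins.tsd,
        "template": ins.template,
    }]
    for child, child_off in zip(ins.children, ins.child_offsets):
        rows.extend(_truth_rows(child, chrom, offset + child_off))
    return rows


def ltr_family(template: ElementTemplate, n_copies: int,
               mutation_rate: float, seed: int = 0) -> list[str]:
    """A set of LTRs diverged iid from one ancestral LTR.

    Unlike :func:`make_ltr_pair`, nothing is protected: the att motifs
    mutate at the same per-position rate as the rest, which is what
    consensus-recovery experiments need.
    """
    rng = np.random.default_rng(seed)
    length = int(round(rng.normal(template.ltr_length_mean,
                                  template.ltr_length_sd)))
    length = max(length, 200)
    ancestor = (template.u3_att
                + random_dna(rng, length - 21, gc=0.45)
                + template.u5_att)
    ancestor = plant_cpg_island(ancestor, template.cpg5, rng)
    ancestor = plant_cpg_island(ancestor, template.cpg3, rng)
    return [_mutate(ancestor, mutation_rate, rng) for _ in range(n_copies)]


def plastic_alignment(n: int, island_mean: float, island_cv: float,
                      rest_mean: float, rest_cv: float, seed: int = 0
                      ) -> tuple[list[str], tuple[int, int]]:
    """Aligned LTR set whose island region has a configured length CV.

    Degapped lengths of the island block (and of the rest) are drawn and
    then rescaled so their sample SD/mean equals the configured CV
    exactly (up to integer rounding); shorter sequences are gap-padded
    within their region's columns.  Returns (alignment, island column
    interval); the island block is G+C-rich so windowed island callers
    can find it.
    """
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    rng = np.random.default_rng(seed)

    def lengths(mean, cv):
        x = rng.normal(size=n)
        x = (x - x.mean()) / (x.std(ddof=1) if x.std(ddof=1) else 1.0)
        return np.maximum(2, np.round(mean + x * cv * mean).astype(int))

    isl = lengths(island_mean, island_cv)
    rest = lengths(rest_mean, rest_cv)
    left = rest // 2
    right = rest - left
    wl, wi, wr = int(left.max()), int(isl.max()), int(right.max())
    rows = []
    for k in range(n):
        rows.append(
            random_dna(rng, int(left[k]), gc=0.40).ljust(wl, "-")
            + random_dna(rng, int(isl[k]), gc=0.65).ljust(wi, "-")
            + random_dna(rng, int(right[k]), gc=0.40).ljust(wr, "-"))
    return rows, (wl, wl + wi)


# ---------------------------------------------------------------------------
# codon alignment simulation

def random_tree(n_taxa: int, mean_branch: float = 0.1, seed: int = 0,
                prefix: str = "t") -> str:
    """Random topology by sequential joins, exponential branch lengths."""
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1, b2 = rng.exponential(mean_branch, size=2)
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def simulate_codon_alignment(
    tree: str | SimpleTree,
    n_codons: int,
    model: str = "M0",
    kappa: float = 2.0,
    omegas: tuple[float, ...] = (0.2,),
    proportions: tuple[float, ...] = (1.0,),
    pi: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Evolve sense codons along a tree under an M0- or M1a-style mixture.

    Branch lengths are expected substitutions per codon.  The state space
    is the 61 sense codons, so stop codons never occur.  Returns sequences
    keyed by taxon label and the true parameter dictionary.
    """
    if isinstance(tree, str):
        tree = SimpleTree.from_newick(tree, require_lengths=True)
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if model not in ("M0", "M1a"):
        raise ValueError("model must be M0 or M1a")
    if model == "M0" and len(omegas) != 1:
        raise ValueError("M0 takes a single omega class")
    if model == "M1a":
        if len(omegas) != 2 or abs(omegas[1] - 1.0) > 1e-12:
            raise ValueError("M1a takes omegas=(omega0, 1.0)")
    if any(w < 0 for w in omegas):
        raise ValueError("omega must be >= 0")
    if len(proportions) != len(omegas) or abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must match omegas and sum to 1")
    pi = uniform_frequencies() if pi is None else np.asarray(pi, dtype=float)
    rng = np.random.default_rng(seed)
    classes = rng.choice(len(omegas), size=n_codons, p=list(proportions))
    states = np.empty((len(tree.nodes), n_codons), dtype=np.int64)
    for k, omega in enumerate(omegas):
        sites = np.flatnonzero(classes == k)
        if sites.size == 0:
            continue
        process = CodonProcess(kappa, omega, pi)
        states[0, sites] = rng.choice(len(pi), size=sites.size, p=pi / pi.sum())
        for idx in reversed(tree.postorder):  # preorder
            node = tree.nodes[idx]
            if node.parent is None:
                continue
            p = process.transition_matrix(node.edge_length)
            cum = np.cumsum(p, axis=1)
            u = rng.random(sites.size)
            parent_states = states[node.parent, sites]
            states[idx, sites] = np.array([
                int(np.searchsorted(cum[s], x)) for s, x in
                zip(parent_states, u)
            ])
    seqs = {}
    for node in tree.nodes:
        if not node.children:
            seqs[node.label] = "".join(SENSE_CODONS[s]
                                       for s in states[node.index])
    truth = {"model": model, "kappa": kappa, "omegas": tuple(omegas),
             "proportions": tuple(proportions), "site_classes": classes}
    return seqs, truth


# ---------------------------------------------------------------------------
# on-disk formats

def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth(truth: pd.DataFrame, prefix: str | Path) -> None:
    """Write the truth table as TSV plus a BED6 of element intervals."""
    prefix = Path(prefix)
    truth.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    with open(prefix.with_suffix(".bed"), "w") as fh:
        for _, row in truth.iterrows():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{row.status}\t0\t+\n")


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)!r}\n")
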