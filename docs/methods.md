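# Methods

This note records the models, conventions and deliberate design choices
behind `delscape`, in the order data flows through the pipeline.

## Synthetic genomes (`simdata`)

The generator emulates the structure of plant chromosomes carrying
Del-like elements, not their full biology. A chromosome is iid
background sequence at a configurable G+C fraction (default 0.44,
typical of plant euchromatin) into which elements are written at
non-overlapping positions.

Each full-length element is `LTR5 + internal + LTR3`, flanked by
identical target-site duplications (TSDs, default 5 bp, range 4–6). The
two LTRs derive from a single ancestral LTR mutated independently, each
at half the configured LTR-pair divergence (default 0.05), so the
expected LTR–LTR identity equals one minus the configured value. LTR
lengths are normal (default mean 2000 bp, SD 100). The ancestral LTR
opens with the 10-bp U3 att (default `TGTAACACCC`, the canonical motif)
and closes with an 11-bp U5 att ending in `CA`; att positions are
protected from the divergence mutations so planted termini stay
verbatim — `ltr_family()` deliberately drops that protection for
consensus-recovery experiments. U5 templates carry `GGG` (type A) or
`TTC` (type B) at positions −8,−9,−10, where −1 is the LTR's final base
(the A of the terminal CA); as a plus-strand substring that triplet is
`u5[1:4]` of the 11-mer.

Optional CpG islands are planted by overwriting an LTR segment with a
block built to meet the %GC and Obs/Exp targets. Enrichment (A/T→C/G,
then CG-dinucleotide conversions) is applied per ~100-bp chunk rather
than block-wide so that every sliding window of comparable size sees a
qualifying signal; infeasible targets (Obs/Exp above roughly 2/gc)
raise an error. Island length is drawn from (mean, SD); SD 0 gives
byte-identical island lengths across copies and hence zero plasticity.

Degenerate copies: *truncated* copies lose a 5'-prefix that destroys
the 5' LTR (they keep no TSD, as post-insertional truncation would
leave at most one flank intact); *solo LTRs* are a single LTR with
TSDs, the recombination product that vastly outnumbers full elements in
real genomes; *nested* insertions are placed only inside the internal
region of an earlier element (never across LTR termini), expanding the
host, whose status becomes `nested_host`. Everything is driven by one
`numpy` Generator seeded from the config, so identical configs produce
byte-identical FASTA and truth tables.

Codon alignments are simulated on a user tree by the same reversible
sense-codon process the selection tester fits (below). The state space
is the 61 sense codons — the rate matrix has no transitions into stop
codons — so stop-free output is structural rather than enforced by
rejection; the resulting distribution is the same. Branch lengths are
expected substitutions per codon. M1a mixtures assign each site to a
class once (iid by the class proportions).

What the generator does **not** emulate: host genes, indels within
coding regions, nucleotide-level similarity between copies of the same
family (each copy draws an independent ancestral LTR, which makes mined
candidates cleanly separable and truth unambiguous), methylation, and
insertion-age structure. Passing recovery tests therefore demonstrate
correctness of the structural logic at realistic divergence, not
performance on real repeat landscapes, where fragmented and
family-correlated copies make mining strictly harder.

## Element mining (`ltr_miner`)

Detection is seed-and-extend: exact 15-mer matches (never crossing Ns)
between prospective LTR copies are grouped by diagonal, clustered, and
extended with an ungapped X-drop walk (+1/−2, drop 20); the pair is
verified with a gapped edit-distance alignment (edlib), identity =
1 − edits / max(len). Exact-diagonal grouping assumes
substitution-level divergence between LTR copies; indel-riddled pairs
are found only via their longest co-linear block, a documented
limitation. Defaults: LTR length 1000–5000 bp, inter-LTR separation
1–15 kb, identity ≥ 0.80, ≥ 3 seeds.

Refinement shifts both LTR copies by a common offset within ±15 bp so
the 5' LTR starts `TG` and the 3' LTR ends `CA` (smallest |offset|
wins); failure flags `termini_ok=False` rather than dropping the
candidate, so downstream stages can quantify refinement failures
instead of silently losing them. TSDs are read off the flanks, longest
identical 6→4 bp match first. Overlapping candidates resolve by highest
identity, then leftmost start — a deterministic ordering.

## Lineage classification (`domain_classifier`)

A transparent position-specific scoring matrix replaces profile-HMM
machinery: per-column log-odds
`log2(((count + pc·bg)/(n + pc))/bg)` with pseudocount 1 and uniform
background, columns > 50% gaps dropped. Elements are translated in all
six frames (standard code); internal stops score as the column's worst
residue, so a frameshift-free domain flanked by stops still wins.
The best ungapped window over all frames and profiles decides the
lineage; equal scores break on lexicographic lineage name. Since
E-value statistics belong to the HMM world, the decision threshold is a
bit score calibrated on shuffled-sequence nulls (max null score +
10 bits by default) — conservative by construction.

## Phylogenetic grouping (`phylo_grouper`)

T92 distances use pairwise gap/N deletion and per-pair θ (the G+C
content of the two sequences at compared sites), matching the model's
stationarity assumption. Log arguments ≤ 0 mark the pair *saturated*:
the entry is set to a configurable ceiling (default 10) and logged, so
one saturated outgroup pair cannot silently poison a matrix. The gamma
variant defaults to shape 1.07 for RT–RNaseH data; 0.8 suits integrase
domains.

Neighbor joining is the standard Saitou–Nei Q-criterion with two
determinism guarantees: ties break on the smallest original-taxon-index
pair, and negative branch lengths clamp to zero (logged). On additive
matrices the algorithm is exact — the test suite checks 100 random
additive matrices against a four-point-condition generator and an
independent implementation (scikit-bio).

Bootstrap resamples alignment columns with replacement; an edge's
support is the percentage of replicate trees containing its
bipartition. Supports are attached to bipartitions, not nodes: when the
tree is rerooted on the outgroup for group assignment, each clade's
support is looked up from the canonical bipartition map built before
rerooting (naive label-carrying across rerooting mis-assigns supports).

Groups are maximal ingroup clades with support **strictly** above the
threshold (default 75), numbered with roman numerals depth-first from
the root. The full ingroup crown — always a clade once the tree is
rooted on the outgroup, and usually well supported — is treated as a
container, not a group, otherwise every analysis would yield exactly
one group. Subgroup delimitation inside groups is exposed as the same
threshold parameter rather than hard-coded.

## Att calling (`att_caller`)

Profiles cover the first and last 40 bases of each LTR (shorter LTRs
are skipped with a warning). The 3' profile is reported in plus-strand
coordinates; column width−1 is the LTR's last base. Information content
is 2 − H(column) bits; the small-sample correction (3/(2·ln2·n)) is off
by default and available as a flag. Consensi use per-column majority
with IUPAC codes at ties — determinism without false precision. Mean
att identity is 100·(1 − mean pairwise p-distance) over the fixed att
window, computed exactly from column counts
(Σ c\_b(c\_b−1)/(n(n−1)) per column equals the all-pairs average); the
windowed (columnar) value is the default report. U5 typing reads the
−8,−9,−10 triplet; any ambiguity there yields `other`.

## CpG profiling (`cpg_profiler`)

Windowed island calling follows the classic cpgplot-style defaults
(window 100, shift 1, %GC ≥ 50, Obs/Exp ≥ 0.6, min length 200). Island
membership uses the *closure* reading: a position is island-like if
covered by any qualifying window; maximal runs ≥ min length are
reported, with %GC and Obs/Exp averaged over the qualifying windows
overlapping the run. This is one of several defensible readings of
windowed island calling, so it is pinned by an exact brute-force
per-window oracle in the tests. Obs/Exp counts CG dinucleotides fully
inside the window and is defined as 0 when #C or #G is 0.

Consensus building drops columns > 50% gaps and breaks majority ties by
fixed A<C<G<T order (logged implicitly by determinism). Patterns follow
the island half (by midpoint): A none, B 5'-half only, C both halves;
islands only in the 3' half — not observed in the lineage this models —
report as `other` with a warning. Heterogeneous subgroups are split
before consensus by single-linkage clustering at ≥ 80% pairwise
identity.

The plasticity ratio maps island coordinates to individual sequences
via alignment columns (the mapping the source data leaves unstated):
per sequence, the degapped length of the island columns and of all
remaining columns; sample SD (n−1) over mean per region.

## Length statistics (`element_stats`)

Internal length is element − 2×LTR; non-positive results are flagged
invalid rather than dropped silently. The outlier filter is a single
pass per subgroup — means and SDs are computed once, |x−mean| > k·SD
(k = 3) removes the record, and the filter is deliberately not iterated.
With SD = 0 nothing is removed (strict inequality). Correlation is OLS
with R² = squared Pearson, the spreadsheet-trendline convention.

## Motif scanning (`genome_scanner`)

Exact matching only, both strands, overlapping occurrences included; a
palindromic-context site yields one hit per strand (a dedup flag
collapses coincident spans, since either convention is defensible for a
text-search protocol). Density is count/length × 5×10⁶ (copies per
5 Mb); windowed tracks use half-open 5-Mb bins keyed by start
coordinate, the last partial bin reported at true width. The
expected-by-chance reference is bin/4¹⁰ per strand under a uniform base
model, doubled for two strands.

Hit validation replaces BLAST E-values with an identity/coverage rule:
the 3-kb flank downstream of the motif *in the hit's orientation* (the
U3 att opens the LTR, so the LTR body lies 3' of the motif; minus-strand
flanks are taken 5'-ward on the plus strand and reverse-complemented)
must contain an edlib infix alignment of a library LTR prefix at ≥ 80%
identity over ≥ 100 bp. An empty hit list reports `None` — undefined,
not 0%.

## Selection testing (`selection_tester`)

Alignment preparation applies two rules in order: sequences with a
contiguous indel > 15 nt (five amino acids) are excluded, then every
codon column containing a gap, stop or ambiguity in any retained
sequence is dropped; both exclusions are recorded on the object.

The codon process is the reversible single-nucleotide-step model with
rates ∝ π\_j, κπ\_j, ωπ\_j, ωκπ\_j and Q scaled to mean rate one;
π defaults to F3x4 with floored positional nucleotide frequencies so
every sense codon stays reachable. P(t) comes from a symmetric
eigendecomposition (√π similarity transform) — faster and numerically
safer than a general expm. Site likelihoods use Felsenstein pruning
over unique codon-column patterns with per-pattern rescaling; mixtures
combine per-class site log-likelihoods by logsumexp.

The input topology and relative branch lengths are taken as given (in
this pipeline, from the NJ stage or the simulation tree); only a global
branch scale is optimised alongside κ, the ω classes and proportions.
This is the main deviation from a full CODEML-style fit, which
re-optimises every branch length per model; it keeps a 200-replicate
calibration experiment at desk scale and is accurate whenever the
relative branch lengths are roughly right. Parameters are transformed
to an unconstrained scale (logs, logits, stick-breaking for M2a
proportions; ω₂ = 1 + e^x keeps the positive-selection class above 1)
and optimised with L-BFGS-B. The fixed multi-start grid
(ω ∈ {0.1, 0.5, 1.5} × κ ∈ {1, 2, 5}, plus a warm start from the
nested null fit) is screened with one likelihood evaluation per start;
full optimisation runs from the best two. lnl convergence tolerance is
effectively 1e−6 via the scaled ftol.

LRTs use plain χ² with df 1 (M0 vs M1a) and 2 (M1a vs M2a) — no 50:50
boundary mixture, mirroring the df the analysis convention states; the
boundary makes the M0-vs-M1a test conservative, which the type-I
calibration test quantifies (rejection ≤ 10% at nominal 5% over 200
replicates of 10 taxa × 100 codons). A negative 2Δl within optimizer
tolerance is truncated to 0 and logged.

Wright's Nc uses frequency-based homozygosity F = Σp² per amino acid,
class means over the standard code's 9 two-fold, 1 three-fold, 5
four-fold and 3 six-fold amino acids, Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
3/F̄₆, capped at 61. One-codon-per-amino-acid usage evaluates to 20
under this formula (2+9+1+5+3), although the bound is conventionally
quoted as 21; the estimator follows the formula and no test asserts the
max-bias bound. An entirely unobserved amino acid is skipped within its
class; an entirely unobserved class is imputed as uniform (1/k) with a
warning.

## Problem sizes and numerics

Default experiment scales — a 10-Mb genome with 20 planted elements for
miner recovery, 50 LTR families of 30 copies at mutation rate 0.2 for
att calling, 50 aligned sequences for plasticity, 100 additive matrices
of 4–12 taxa for NJ, 20 taxa × 500 codons for parameter recovery and
200 replicates of 10 taxa × 100 codons for LRT calibration — are the
package's chosen desk-scale study conditions; all are parameters, not
constants. Key tolerances: NJ additivity 1e−8, T92↔K80 reduction 1e−10,
pruning vs brute-force likelihood 1e−8, ω recovery ±0.05, plasticity
recovery ±0.02, nesting inequalities 1e−4.

## Known limitations

Mining assumes co-linear LTR copies (no indel-aware chaining);
classification has no insert/delete states and no E-values; NJ is
O(n³)-per-join Python, comfortable to a few hundred taxa, not
thousands; branch lengths are not re-optimised per codon model; the
generator's independence of copies makes recovery tests easier than
real repeat landscapes; and CLI plotting mirrors of the logo/density
figures are not included (the TSV outputs are logo- and plot-ready).
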