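# Methods

This note records the models, parameter choices and numerical conventions
behind `invscan`, and what the synthetic study system does and does not
emulate.

## Coordinates

All internal coordinates are 0-based half-open. Human-readable reports print
1-based closed coordinates and say so in their header; BED output is 0-based
half-open as the format requires. Minus-strand anchors store both intervals in
ascending order; the query interval read forward matches the reverse
complement of the target interval.

## Anchoring and chaining

Anchors are maximal runs of shared k-mers. k-mer occurrence is counted per
sequence over both strands, and a k-mer is used only if it occurs at most
`max_occurrences` times (default 1) in *each* sequence; k-mers containing N
are skipped rather than treated as wildcards. The defaults (k = 21, unique
anchors) were chosen because uniqueness automatically masks repeat families —
in particular the inverted repeat cassettes that flank the simulated
inversion, standing in for the resistance-gene-family repeats that confound
real comparisons. The two cassette copies make every cassette k-mer occur
twice in the wild genome, so cassette regions carry no anchors and breakpoint
intervals come out anchor-free, as intended.

Chaining is greedy in target order: an anchor joins an open chain of its
strand when the target gap is ≤ `max_gap` (default 10 kb), the diagonal drift
is ≤ `max_diag_drift` (default 2 kb), and query order stays monotone
(increasing for `+`, decreasing for `−` chains). The diagonal is
`t_start − q_start` for `+` anchors and the anti-diagonal `t_start + q_end`
for `−` anchors, both constant along a collinear run. A full dynamic-
programming chainer is unnecessary at region scale (≤ a few Mb); greedy
chaining with a drift bound recovers the same blocks. One operational
constraint follows from the design: `max_gap` must stay below the smallest
inversion of interest, otherwise the forward flanks chain straight across the
flipped segment. The defaults (10-kb gap, 10-kb minimum inversion size) are
mutually consistent; toy-scale analyses must scale `max_gap` down accordingly.
Blocks with fewer than `min_block_anchors` anchors are dropped; region-scale
analyses use 3 to keep isolated spurious k-mer hits (expected ≈ 0.2 per 1-Mb
pair at k = 21) from splitting a minus run or creating phantom blocks.

An inversion call is a maximal run of `−` blocks flanked by `+` blocks or a
sequence end, with target span ≥ `min_size` (default 10 kb). Nested flips
inside a minus run are not called separately. Breakpoint intervals are the
anchor-free target gaps between the inverted core and its forward flanks —
the caller reports intervals, never single-base breakpoints, because anchor
evidence only bounds the transition.

## Scaffolding

Each scaffold is placed by its anchor chains against the reference.
Orientation is the strand with the majority of anchored coverage; the
minority coverage is recorded, because a scaffold spanning an inversion
breakpoint legitimately chains in both orientations. Each scaffold *edge* is
projected through the same-orientation block nearest that edge in query space
(blocks under 10% of the dominant block's coverage are ignored for the
projection); this keeps gap estimates accurate even when the scaffold's
interior rearranges. Gaps are the projected distances between consecutive
scaffold ends; negative projections (overlaps) report 0 with an annotation.
Gap estimation is by reference projection — there are no sequencing reads to
close gaps with — so estimates inherit error from indel divergence between
the genomes, and the tests use tolerance ±2(k−1) accordingly. Superscaffolds
concatenate oriented scaffolds with N runs (minimum 1 N per gap, as AGP
requires a positive gap part) and are described by AGP v2.0 rows.

## Crossover parsimony

An F2 individual's two haplotypes are unphased. Each genotype code constrains
the ordered haplotype pair at a marker: A → {(a,a)}, B → {(b,b)},
H → {(a,b),(b,a)}, AH → {(a,a),(a,b),(b,a)} (dominant scoring: A or H, never
B), missing → all four. The minimum crossover count for a vector under a
marker order is the cheapest path through these state sets where a step costs
the number of haplotype positions that switch; the dynamic programme over 4
states is exact, and the test suite checks it against exhaustive enumeration
over every genotype vector of length 6. Consequences of the model worth
noting: AH is a relaxation of both A and H (never increases the minimum), and
a "recombinant individual" is one whose *forced* minimum is positive, so AH
ambiguity resolves conservatively to the non-recombinant phase — matching how
dominant CAPS assays are read in practice.

Candidate orders are the reference order plus all contiguous-segment
reversals — the inversion hypothesis class — with optional exhaustive search
for ≤ 7 markers. Ties rank the reference first, then the smaller reversed
segment, then lexicographic permutation. The total is invariant under full
order reversal, so a winner is always reported up to mirror image.

## Two-point genetics

`r_per_gamete` is the summed pairwise minimum crossover count over
2 × n_informative gametes; map distances use Haldane's function
cM = −50·ln(1−2r) (r ≥ 0.5 reports an unbounded flag). Haldane (not Kosambi)
matches the no-interference simulator; interference would need a different
map function, exposed as an obvious single point of change. The estimator has
a known mild downward bias: with two independent gametes per F2, the expected
pairwise minimum is 2r − r² (the double-recombinant gamete pair (ab, ba)
collapses to an H,H genotype scoring 0), so a 4.5-cM interval is estimated at
≈ 4.4 cM on average — well inside the variation between real crosses.

Suppression detection flags a marker pair iff zero recombinants were observed
*and* the expectation makes that improbable: with expected map length =
physical distance × genome-wide cM/Mbp converted through Haldane to r,
the flag requires (1−r)^(2n) < α (default α = 0.05). Pairs with too-small
expectations (short intervals, few individuals) are never flagged.

## Meiosis simulation

Crossovers per inter-marker interval are Poisson(d_cM/100) — Haldane's model,
no interference; the paper-scale populations give no basis for fitting an
interference parameter, and Poisson is the simplest defensible choice. The F1
carries one haplotype per parent; F2 individuals take two independent gametes
(no selfing or segregation distortion); generations beyond 2 self repeatedly
with independent meioses. Suppression is absolute: a meiosis of an individual
whose two haplotypes carry different chromosomal arrangements receives zero
crossovers inside the suppression intervals (partially overlapping intervals
keep their unsuppressed remainder, and realized crossover positions are drawn
only there). A `halo_cM` parameter (default 0) widens each suppressed
interval, because in real crosses the suppressed block can extend beyond the
physical inversion; no value is asserted by default. Arrangement homozygotes
recombine freely — their crossovers exchange identical-origin segments, so no
observable recombinant genotypes ever arise inside the block, which is why
the zero-recombinant guarantee survives selfing to F4 and beyond. Dominant
markers collapse {A, H} to AH at genotype-calling time.

## Synthetic genome pairs

`derive_wild_genome` applies, in order: substitutions at `snp_rate` (default
0.02, the divergence scale of congeneric wild relatives), short indels
(1–5 bp, insertion/deletion equiprobable) at `indel_rate` (default 0.001),
reverse-complementation of the inversion segment, insertion of inverted
repeat cassettes at both flanks (default 3 kb at 95% identity, emulating the
flanking resistance-gene repeats), and optional N runs (200–2000 bp)
emulating assembly gaps. Rates above 0.2 are rejected as degenerate. A
piecewise-linear reference→wild coordinate map is maintained through every
edit, so realized breakpoints, introgression homology and marker positions
are exact ground truth, not approximations. The cassettes are inserted into
the wild genome only (the reference is an input, not a product); uniqueness
filtering masks them regardless, and inversion-boundary tolerances are
`cassette_len + k` on the target side. GC content defaults to 0.36,
reflecting AT-rich Solanaceae euchromatin. Draft fragmentation deletes the
gap bases at each break and emits scaffolds in shuffled order with random
strand flips — a pipeline must not assume draft orientation.

What the generator does **not** emulate: realistic gene models (cassettes are
arbitrary inverted repeats), sequencing reads or assembler behaviour beyond
fragmentation, segregation distortion, genotyping error or missing data in
simulated crosses, and interference in meiosis. Passing recovery tests
therefore demonstrates correctness of the inference machinery under clean
divergence models, not robustness to assembly artefacts or marker error.

## Diagnostic PCR

Primer sites are exact by default (`max_mismatches = 0`), keeping predictions
deterministic; when mismatches are allowed, the three 3′-terminal bases must
still match exactly, as polymerase extension requires. A product needs a
convergent arrangement — one primer on the plus strand upstream of the other
on the minus strand (in either assignment, so predictions are strand-
symmetric) — with length ≤ `max_product_len` (default 5000 bp, the boundary
between standard and long-range PCR; longer convergent arrangements are
reported as `over_max_len` rather than silently dropped). Same-orientation
and divergent site pairs yield nothing.

Junction-diagnostic pairs are designed the way breeders design them: scan
primer-length windows outward from the junction on the carrier template and
take the first window absent (both strands) from the specified off-target
templates. A template then amplifies only if it carries both sides of the
junction, which reproduces the canonical presence/absence pattern — the
junction pair amplifies only the introgression line, the reference-designed
pair only the reference.

## Breakpoint localization

A clone-sized query is chained against the reference; every query-adjacent
block pair that switches strand or jumps more than `jump_threshold` (default
20 kb) beyond what the query gap explains is a breakpoint call. Both triggers
matter: a breakpoint can manifest as a strand flip or as a positional jump
between loci that are hundreds of kb apart on the reference yet adjacent in
the query. The call reports the anchor-free query interval and the flanking
reference loci with strands, plus the collinear prefix length from a
user-supplied query position (e.g. a primer site).

## Problem sizes and determinism

Recovery experiments run on 1-Mb regions with 200-kb inversions across 20
seeds, crosses of 88–11,000 individuals, and a 120–150-kb system for the
PCR/breakpoint demonstrations — sizes at which every stage's behaviour is
identical in kind to the multi-Mb case while the whole suite remains
desk-scale. All randomness flows from explicit seeds; the pipeline derives
per-stage seeds from one master seed by fixed documented offsets, and
identical configurations are byte-reproducible.

## Known limitations

- The anchor chainer is greedy; adversarial repeat structures that would
  require DP chaining are excluded by the uniqueness filter rather than
  resolved.
- Gap estimates are reference projections and drift with indel divergence;
  insertions falling inside a deleted gap window change the projected
  distance by construction.
- The candidate order space is single-segment reversals (plus optional
  exhaustive ≤ 7 markers); multi-segment rearrangements are out of scope, as
  is multipoint maximum-likelihood map construction.
- In-silico PCR scores no thermodynamics (Tm, dimers, degenerate bases);
  site presence and orientation only.
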