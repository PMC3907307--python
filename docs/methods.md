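# Methods

## Model

A fold-back inverted duplication is parameterized by four coordinates on a
chromosome of length `L` (0-based, half-open everywhere in this package):

- `b` — position of the initiating double-strand break; `[b, L)` is lost;
- `e ≤ b` — the effective end after 5'→3' resection: the distal-most
  retained base of the disomic region is `e − 1`;
- `d < e` — the fold-back anneal point: the resected 3' overhang pairs
  intrastrand where the sequence just below `e` is reverse-complementary to
  the sequence just above `d`;
- `p` — the position of the second break, suffered by the dicentric during
  a breakage-fusion-bridge cycle, with `cen < p < d`.

Fill-in and replication of the folded-back end give the dicentric
`ref[0:e] + revcomp(ref[0:d])`; the break at `p` yields the monocentric
inverted-duplication product `ref[0:e] + revcomp(ref[p:d])` and a sibling
simple terminal deletion `ref[0:p]`. In reference dosage the product is
2 copies on `[p, d)` (duplication), 1 on `[0, p)` and on `[d, e)` (the
disomic spacer, size `s = e − d`, the fold-back loop), 0 on `[e, L)`
(terminal deletion). The free end is then stabilized in one of three modes:
telomere healing (`(TTAGGG)n` appended), translocation (terminal segment of
a donor chromosome appended), or ring formation (fusion to the uncapped
p-arm end of the same chromosome, giving a circular derivative).

## Microhomology operators

Two related statistics appear:

- `junction_mh(seq, e, d)` — the junction-level operator: the maximal run
  of Watson–Crick pairings `seq[e−1−i] : seq[d+i]`, capped at
  `⌊(e−d)/2⌋` so the paired blocks cannot cross. This is the microhomology
  a fold-back anneal uses, and exactly the query overlap a split alignment
  of the derivative recovers.
- `inverted_mh_self(S)` — the null-model statistic applied to a drawn
  spacer `S`: the largest `k` with `suffix_k(S) == revcomp(prefix_k(S))`,
  capped at `⌊|S|/2⌋`. It equals `junction_mh(S, |S|, 0)`.

A third, block-anchored comparison (`inverted_mh_block`: largest `k` with
`seq[e−k:e] == revcomp(seq[d−k:d])`) is provided as a documented separate
operator; it is not nested in `k` and is not used by the pipeline. `N`
pairs with nothing, including `N`.

## The maximal-shift breakpoint convention

When the junction carries `k` bp of microhomology, the breakpoint pair
`(e, d)` is ambiguous: the derivative sequence is invariant under
`(e, d) → (e+1, d−1)` whenever `ref[e]` pairs `ref[d−1]`, and each such
shift changes the apparent spacer by 2 bp. Both the simulator's truth
records and the analyzer's calls therefore use the **canonical maximal
forward shift**: shared junction bases are attributed entirely to the
forward (disomic) side, taking the largest admissible `e`. With the same
convention on both sides, breakpoints, spacer size and microhomology
round-trip exactly; this is what makes the "exact spacer recovery"
acceptance property well-posed.

The same rule is applied at resolution junctions: bases shared between the
inverted segment and the appended telomere array (or donor segment) are
attributed to the reference-aligned (left) side.

## Synthetic genomes

`generate_reference` draws iid sequence at a configurable base composition,
caps every chromosome with `(CCCTAA)n` / `(TTAGGG)n` telomere arrays
(default 500 units), and places the centromere at a configurable fraction
of the length (default 0.1) — the centromere is a coordinate, not a
sequence feature; it only decides which breakage products are monocentric.
Repeat pairs (Alu/LINE-like) are planted by copying a segment, optionally
reverse-complementing it, and applying exactly `round((1−identity)·length)`
point substitutions at uniform positions, so the realized identity is the
requested one up to the integer rounding of the substitution count.
Substitution-only divergence keeps all junction arithmetic exact and is
what "percent identity over an alignment length" measures. A circular
16,569-bp mitochondrial-like donor serves only as an insertion source.

These genomes are idealized: no GC heterogeneity along the chromosome, no
genome-wide interspersed repeat background (repeats exist only where
planted), no sequencing error in amplicons or reads. Consequently the
analyzer can use an exact, ungapped seed-and-extend aligner, and null-model
tail frequencies follow the iid law `P(mh ≥ k) = 4⁻ᵏ` — both of which are
tested, not assumed.

## Split alignment and junction calling

Amplicons (default 400-bp flanks around a junction) are aligned with a
sorted numpy k-mer index (k = 20) over all forward-strand k-mers; minus
strand hits come from querying the reverse complement. Seeds with more
than 50 genomic hits are discarded as uninformative (this automatically
removes telomere-array seeds). Each seed is extended to a maximal ungapped
local alignment and deduplicated by diagonal. The call uses the alignment
reaching furthest left on the query and the one reaching furthest right:
query overlap = microhomology, query gap = insertion (the two are mutually
exclusive by construction). Classification order: telomeric right side
(≥ 2 complete `TTAGGG` units anchored at the junction, any phase) →
inversion-telomere; different chromosomes → inversion-translocation; same
chromosome, `+` then `−`, reverse coordinate proximal → disomy-inversion
with spacer `e − d`; anything else unresolved, with a diagnostic (a
`−`-then-`+` geometry is flagged as consistent with a ring fusion).

Insertion origins are located by scanning ±1 kb around each breakpoint for
an ungapped match at ≥ 90 % identity in either orientation, then the
circular mitochondrial donor; insertions < 4 bp are reported
unclassifiable. Hybrid-repeat calls require both breakpoints inside the
two copies of one annotated inverted pair, and report the pair's homology
length and realized identity.

## CGH simulation and segmentation

Probes are placed every `probe_spacing` bp; expected log2 test/reference
ratios on a diploid with one rearranged homolog are 0 (disomy),
`log2(3/2) ≈ +0.585` (duplication) and `−1` (deletion), plus Gaussian
noise. Segmentation thresholds a 5-probe running mean at the state
midpoints (−0.5, +0.2925), merges segments shorter than 3 probes, then
refines each boundary against the raw probes by minimizing squared error.
Refinement may slide a boundary far enough to empty a segment: the
smoothing ramp at a direct duplicated→deleted step fabricates a short
"disomic" run whose raw probes belong to the flanking states, and removing
it is what keeps spacer detection honest at coarse probe spacing. The
spacer estimate is the distance from the most distal duplicated probe to
the most proximal deleted probe, and counts as *detected* only if a
disomic segment lies between them — a 3,428-bp spacer is detected at
200-bp spacing and invisible at 75-kb spacing.

## Null model and enrichment statistic

The null draws `N` spacer intervals near chromosome q-termini (lengths
uniform on `[100, 70,466)`; distal end uniform within 5.5 Mb of the
q-terminus, excluding the telomere cap) and computes `inverted_mh_self` for
each. With `c` of `N` draws at or above the microhomology threshold
(default 2 bp) and `m` observed junctions all meeting it, the empirical
p-value is `C(c, m) / C(N, m)`, computed as the telescoping product
`∏_{i<m} (c−i)/(N−i)` for numerical stability. This is the probability
that a uniformly drawn `m`-subset of the simulated junctions consists
entirely of threshold-meeting ones. Note the one-base-window difference
between the null statistic (a spacer's own two ends) and the junction
operator (spacer end versus the bases just proximal of the spacer); the
discrepancy is recorded in the null report metadata.

The packaged cohort table (`foldback/data/cohort_junctions.tsv`, 25
subjects) carries deletion/duplication/spacer sizes and indicator columns
for which junction classes were sequenced; `cohort_stats` summarizes it
(spacer median 3,428 bp, range 766–70,466 bp; 21 + 10 + 3 = 34 sequenced
junctions).

## Parameters and problem sizes

| Parameter | Default | Rationale |
|---|---|---|
| amplicon flank | 400 bp | enough for unique 20-mer anchors on both sides |
| seed k / stride / max hits | 20 / 10 / 50 | unique in tens-of-Mb iid genomes; skips telomere arrays |
| insert mean/sd, read length | 400 / 40 / 100 | typical short-read library; discordance cut at ±4 sd |
| probe spacing | 200 bp | the fine-array design point; 75,000 models clinical arrays |
| null draw window | 5.5 Mb of q-terminus | the terminal-deletion regime being modeled |
| spacer length range | 100–70,466 bp | spans the cohort's observed spacers |
| telomere cap | 500 units | large enough that caps are unambiguous telomeric runs |

Test problem sizes (16-Mb cohort chromosome for the 200-simulation
round trip, 50-Mb chromosome for the worked example, N = 10,000 null
draws) are this package's own choices, sized to finish in minutes on one
CPU while keeping every statistical check well-powered.

## Determinism

Every entry point takes a single integer seed. Stage-level generators use
sub-seeds `sha256(f"{seed}:{stage}") mod 2³¹`, so adding one stage never
perturbs another's draws. Identical seeds reproduce byte-identical run
directories (verified via `manifest.json` SHA-256 digests).

## Limitations

- Genomes are iid with planted features; repeat-background effects on
  alignment specificity and on the null distribution are out of scope.
- Amplicons and reads are error-free; the aligner is exact and ungapped by
  design and would need replacement for noisy data.
- The simulator models one rearranged homolog on a diploid background;
  mosaicism and multi-step BFB histories beyond a single break are not
  modeled.
- Ring-fusion junctions are deliberately *not* auto-called: the analyzer
  flags the geometry and leaves classification to the caller, since a
  minus-then-plus split is also consistent with other structures.
- The centromere is a coordinate without sequence; centromeric alignment
  artifacts cannot arise by construction.
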