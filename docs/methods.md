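# Methods

## Array model and parsing

A CRISPR locus is modelled as `leader · (repeat · spacer)ⁿ · repeat ·
trailer`: n spacers bounded by n+1 direct-repeat copies, a leader 5′ of
the first repeat and a trailer after the terminal one. `parse_array`
locates repeat copies as non-overlapping occurrences with at most
`max_repeat_mismatch` substitutions (default 2), scanned left to right,
greedy leftmost. Indels inside repeats are deliberately out of scope:
a repeat degraded by indels makes the parse fail loudly (an inter-repeat
segment outside the spacer length window, default 20–45 nt) rather than
silently mis-segment. Per-copy substitutions are recorded, so the parse
is loss-free: concatenating leader, observed repeat copies, spacers and
trailer reproduces the input byte-exactly, and parsing is idempotent
under re-serialization. Orientation is the caller's responsibility
(loci are supplied leader-first). N bases count as mismatches in every
exact-match context and are excluded from GC denominators.

Spacer numbering: internally canonical from the leader-proximal end
(`leader_index`, 1 = newest); the trailer-anchored convention used in
published spacer maps is carried alongside (`trailer_index`), the two
summing to n+1. Reports use trailer numbering by default.

## The diff algorithm

Ancestor and BIM arrays are compared as sequences of spacer tokens;
token equality is a spacer match at `max_mismatch` substitutions
(default 0 — both arrays come from the same strain's Sanger data). The
global alignment scores +2 per matched token and −1 per inserted or
deleted token, with substitution forbidden: an in-place spacer
replacement is represented as deletion + acquisition, since replacement
is not a described acquisition mechanism. Among co-optimal alignments
the canonical one is the lexicographically smallest move string under
insertion < match < deletion, read leader to trailer. This is computed
exactly by a suffix-score dynamic program with a greedy front-to-back
traceback that takes the smallest co-optimal move at each step.

The tie-break is the scientifically loaded choice. When an acquired
spacer duplicates its neighbour (e.g. BIM array `[x1, x1, x2, …]`), the
acquisition could sit at array position 1 or 2 at equal score; the
canonical alignment places it leader-proximal, so a 5′-end (polar)
placement is chosen whenever co-optimal. Polar acquisition is the
mechanistic default, so this never over-calls the rarer ectopic class.
An acquisition is *polar* when every array position on its leader side
is itself an acquisition (a contiguous new 5′ block), else *ectopic*;
a BIM is labelled ectopic if any of its acquisitions is. Acquired
spacers matching an ancestral spacer are flagged `duplicate_of`. The
tests verify the canonical alignment against exhaustive enumeration of
all monotone token matchings on 500 random small instances, and the
edit-script application invariant (ancestor ⊕ diff = BIM) on hundreds
more.

## Protospacer search, PAM and targeting

Spacer→genome matching is substitution-only (Hamming) over fixed-length
windows on both strands, vectorized with numpy; every window within
`max_mismatch` (default 3, bracketing the reported 27/30 and 28/30 near
matches) is a hit, with forward-strand coordinates. The PAM is taken as
the 7 nt immediately 3′ of the protospacer *on the protospacer strand*
(for minus-strand hits: the forward window 5′ of the hit, reverse-
complemented), truncated-and-flagged at genome edges. The side and
length are configurable (`pam_len`, `pam_side` in `RunConfig`); 3′/7 nt
matches the 7-symbol NNAGAAW consensus of this system. Consensus
rebuilding calls a single base per column when its frequency reaches
`threshold` (default 0.9), otherwise the smallest IUPAC degeneracy class
covering every base with frequency ≥ 1−threshold, with N as fallback.
Targeting prediction implements the perfect-match rule: resistance
requires 0 mismatches over the full spacer plus a consensus PAM;
anything less is reported as a non-targeting near match.

## Leader and insertion-context analysis

`compare_leaders` globally aligns the *full* leaders with unit edit
costs and reports edits falling in the 3′-terminal window (default 10
nt), positions counted from the 3′ end (−1 = last base). Aligning full
sequences, rather than clipping both to a fixed window first, avoids a
manufactured edge edit whenever the leaders differ in length — the
motivating comparison is exactly a leader pair differing by one terminal
base (`…ATTTGAG` vs `…ATTTGA`). Traceback prefers match > substitution
> deletion from the 3′ end, so terminal indel runs are reported at their
3′-most position; the reported distance is cross-checked against an
independent edit-distance library in the tests.

For each acquisition, the insertion context is the 3′-terminal
`n` nt (default 7, the length of the canonical leader anchor ATTTGAG) of
the unit immediately leader-side of the new spacer in the BIM array —
the leader itself for first-position acquisitions, otherwise the
upstream spacer. Positional profiles count nucleotides at 3′-anchored
positions over a context set. Because a missing −1 anchor guanine can be
compensated by a repeat whose first base is G, the statistic
"G at −1 OR repeat starts with G" is computed as a separate column, not
merged into the raw −1 fraction. The pipeline profiles distinct upstream
units (a site hit by several BIMs contributes once), mirroring the
per-site presentation of such analyses; the per-BIM contexts are all in
the TSV output.

## Simulators and the packaged fixture

`generate_genome` draws i.i.d. bases at a target GC (default 0.39, the
GC content of the relevant *cos*-type phage genomes; default length
34 500 nt, their size scale) and plants non-overlapping 30-nt
protospacers, one per equal-width bin at a random offset, each followed
by a PAM drawn uniformly from NNAGAAW-conforming strings.
`generate_ancestor` emits arrays of pairwise-distinct random 30-nt
spacers (default 23, the ancestral array size of the modelled strain)
around a fixed synthetic 36-nt repeat. `simulate_cohort` plants events
per a `CohortSpec` whose defaults are the published cohort composition
(23 BIMs; 14 polar-only of which 12 single; multi-polar BIMs of 2 and 3
acquisitions duplicating the newest ancestral spacers; deletion blocks
of 1 and 8 spacers; 9 ectopic BIMs), sourcing every novel spacer from an
unused planted protospacer site so the full pipeline round-trips. In
`anchored` mode, ectopic sites are drawn only downstream of spacers
whose 3′ end matches the anchor pattern (default `AN`: adenine at −2);
in `uniform` mode, uniformly over internal boundaries. All generators
are deterministic given their seed (NumPy `default_rng`).

What the simulator does *not* emulate: codon/dinucleotide structure,
sequencing error, PCR chimeras, repeat-internal indels, or phage genome
architecture (modules, ORF boundaries are synthetic evenly spaced
spans). Passing recovery tests therefore demonstrate the correctness of
the parsing/diffing/mapping machinery under clean planted events, not
robustness to noisy real Sanger reads — for real data the repeat must be
supplied explicitly and tolerances widened deliberately.

The packaged fixture (`build_worked_example`, seed 42) reproduces the
published cohort *structure* exactly (counts, sites, duplication and
deletion multiplicities, leader difference, context conservation: A at
−2 in 5/5 upstream units, G at −1 in 4/5 with the fifth compensated by
the repeat's leading G). Its nucleotide sequences are synthetic
stand-ins: the deposited spacer/repeat/leader sequences are not
reproduced. The ten unnamed single-polar BIM ids and the deletion-block
positions are invented; only their counts are meaningful. The repeat is
a synthetic 36-mer chosen to start with G to realise the compensation
case.

## Numerical and design choices

- Coordinates: 0-based half-open internally, 1-based inclusive in
  user-facing tables (BED-style exports would stay 0-based).
- `detect_repeat` extends the top k-mer (k = 18, ≥ 3 occurrences) while
  a flanking column agrees in ≥ 90 % of occurrences; with few repeat
  copies a single divergent copy can stop extension early, so the
  detector is a convenience and the parser always accepts an explicit
  repeat.
- In-silico PCR pairs each forward-primer site with the nearest
  downstream reverse site (real PCR favours the shortest product) and
  flags multiple products; absent primers give an empty result, not an
  error. Primer matching is exact by default.
- ORF scan: starts ATG/TTG/GTG, first in-frame stop, ≥ 30 aa (start
  codon counted, stop excluded), longest ORF per stop-codon group, all
  six frames; ORFs without an in-frame stop are discarded; linear by
  default with a circular option that wraps the origin. Exact ORF-count
  reproduction for annotated deposits is not promised — published counts
  depend on annotation judgment (RBS support, nested starts).
- Cohort-recovery guarantees hold for planted events away from
  pathological ambiguity (e.g. an ectopic insertion of a spacer
  duplicating its own downstream neighbour is indistinguishable from a
  more leader-proximal placement and is resolved canonically).
- Test problem sizes (500 diff-oracle instances, 200 planted protospacer
  cases, ≤ 5 kb ORF oracles, 50 random cohorts, 200-event context
  cohorts) were chosen as the smallest sets that exercise every code
  path and tie-break while keeping the suite fast on one CPU.
- The uniform-mode −2-adenine fraction is assessed on an 80-spacer
  ancestor: with very small ancestors the fraction is dominated by the
  ancestor's own base composition rather than the site-sampling
  mechanism under test.

## Known limitations

No de-novo CRISPR discovery, cas typing, CR2/CR4 loci, phylogenetic
inference from spacer content, crRNA seed-region weighting,
interference-efficiency modelling, or read-level (FASTQ) simulation.
Repeat matching tolerates substitutions only. Leader comparison assumes
globally alignable leaders (same locus, closely related strains).
Statistical testing of motif enrichment is out of scope — the relevant
sample sizes (five contexts) support only descriptive fractions.
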