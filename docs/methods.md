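# Methods

## Problem and model

`fmmap` maps short DNA reads onto a reference genome, reporting *every*
reference location where the read aligns with at most `e` edits — mismatches,
insertions of reference bases, and deletions of read bases. It is an
all-mappings tool in the spirit of FM-index backtracking aligners, not a
best-hit mapper: the intended use is as a fast preprocessing or seeding stage
in front of a local-alignment mapper, where completeness at a fixed edit
budget matters more than scoring refinement.

The index is a classic FM-index. For the sentinel-terminated reference
`X$` (with `$` sorting below `A < C < G < T`) we keep

* the suffix array `S` and its inverse `R` (`R[S[i]] = i`),
* the BWT `B[i] = X[(S[i]-1) mod n]`,
* `C(a)` — the number of BWT symbols lexicographically smaller than `a`,
  with the sentinel excluded from the counts,
* `O(a, i)` — the number of `a` in `B[0:i]`.

Backward search maintains the SA rank interval `[k, l]` of the suffixes
beginning with the current pattern; prepending symbol `a` updates it as

    k' = C(a) + O(a, k) + 1        l' = C(a) + O(a, l+1)

(the `+1` absorbs the sentinel suffix at rank 0). `res = l - k + 1` is the
occurrence count of the current string and can only shrink. The same
structures are kept for the reversed reference, so a read can also be scanned
left-to-right ("forward" search = backward search of the reversed pattern on
the reversed-text index); no bidirectional index is used, and a
`change_direction` subroutine re-expresses a live interval in the other
index by locating each rank, mapping coordinates through
`p' = n - 1 - p - m` (match length `m`, sentinel-inclusive `n`) and
re-ranking with the other side's inverse SA.

## Compressed structures

`O` is stored as, per base, `ceil(n/w)` bit vectors of `w` bits
(least-significant bit = lowest BWT position) plus one running count per
vector; a query is one displacement read plus a masked popcount. `S` and `R`
are sampled every `r` positions (`Scomp[k] = S[k·r]`, `Rcomp[k] = R[k·r]`)
and reconstructed with the LF-step

    psi_inverse(i) = C(B[i]) + O(B[i], i+1),     S[psi_inverse(i)] = S[i] - 1.

`sa_lookup(k)` walks `psi_inverse` until it reaches a rank whose suffix
position is a stored multiple of `r` — the rank image of `Rcomp` marks
exactly those ranks, which bounds the walk by `r` steps and keeps it away
from the sentinel row. `isa_lookup(k)` starts from the sample at
`k + (r - k mod r) mod r` and walks back; positions in the final partial
block start from the sentinel suffix (position `n-1`, always rank 0).
Defaults `w = 64` (machine word) and `r = 16` trade a 16-fold SA memory
reduction for short reconstruction walks.

## Inexact search

Mismatches `M(b)` and insertions `I(b)` consume a reference base through one
`search_iteration`; a deletion `D` skips a read base without an iteration.
Insertions are always recorded at the read position *following* the inserted
base, so the same physical alignment gets the same edit list in either scan
direction. A hit's location is the first reference position its alignment
consumes; alignments are anchored so that this base is consumed by a match
or mismatch (leading read-deletions are allowed and charged; an alignment
beginning with a reference-base insertion is the same alignment anchored one
position later and is never reported separately).

Four pruning devices control the search tree, and none of them removes a
mapping location:

1. **Dead intervals.** Branches with `k > l` are discarded.
2. **Shrink-gated branching.** Error branches are opened only where
   extending with the read's own symbol loses occurrences (`res' < res`).
   If no occurrence is lost, every occurrence of the current string is
   preceded by the read's symbol, so alternative edits either die
   immediately or re-label an alignment that is found elsewhere — this is
   what collapses the several equivalent deletions of a homopolymer run to
   a single canonical placement. One structural exception: within the
   left-edge zone (current position + accumulated errors < `e`, i.e. where
   an edit chain could still reach the read start) a branch candidate is
   always opened, because an indel in a run that touches the read's left
   edge shifts the mapping position and its cheaper relabelling lies outside
   the read.
3. **Consecutive-edit rules.** Adjacent edit pairs equivalent to a single
   cheaper edit are refused: an insertion next to a deletion (either order)
   is a mismatch; a deletion adjacent to a mismatch whose base equals the
   deleted read base re-labels a single deletion; an insertion adjacent to a
   mismatch at the insertion's base re-labels a single insertion. The I-M
   rule is suspended when its fold target would be a leading insertion (see
   above) — again only inside the left-edge zone.
4. **Lower-bound (D) pruning.** Before each step a vector `D` is built by
   growing a window over the read with single `search_iteration`s and
   charging one edit every time the window stops being a reference
   substring (the window then restarts). Disjoint non-substring windows each
   force an edit in *any* alignment, so `D` is an admissible bound and
   cutting a partial result when `errors + D[position] > e` is lossless.
   One vector bounds the unscanned prefix `W[0..i]` (consulted while
   scanning leftwards), a second the unscanned suffix `W[i..L-1]`
   (consulted rightwards); the exact segment of the step is zero.

### Single-pass and segment-stepped drivers

`search_prototype` runs one backward scan of the whole read with the gates
above. It is correct but slow while the interval is still wide (the first
~`log4 n` symbols), because early branches almost always survive.

`search_complete` removes that start-up cost. The read is divided into
`e+1` near-equal segments (each at least `segsize` symbols, so the largest
supported budget for a read of length `L` is `floor(L/segsize) - 1`; for a
250 bp read with the 31-symbol segments appropriate for a human-scale
genome that is `e = 7`). Step `s` (for `s = 0..e`):

* exact-searches segment `s` (backward for `s >= 1`, forward for `s = 0`);
  if the segment is absent from the reference the step is skipped;
* extends leftwards through segments `s-1 .. 0` with inexact search, each of
  which must end up containing at least one error — placements leaving an
  earlier-step seed segment exact were already enumerated by that step, so
  partial results reaching a segment boundary with no error in the segment
  are dropped;
* changes direction once and extends rightwards to the read end.

For a given alignment, attribute each edit to the segment containing its
read position: the alignment is enumerated exactly by the step whose index
is the smallest segment with zero edits (which exists because there are
`e+1` segments and at most `e` edits). The union over steps is therefore the
complete mapping set, and each alignment is produced once. Results are
finally de-duplicated on (position, canonical edit list) and sorted by
(error count, position).

Exploration is breadth-first in error levels — round `j` of a step holds
partial results with exactly `j` edits — except that a ramification whose
budget is exhausted (the last level) is completed depth-first immediately,
avoiding queue traffic ("hybrid" traversal; a pure-BFS mode exists and
produces identical results).

### Bounded stacks

The partial-result lists are capped (default 50 000 entries, following the
tool's intended operating point; 500 gives a fast best-alignments mode).
On overflow the entry with the most errors (ties: fewest analysed symbols)
is shed first. Because exploration is error-level ordered, the search then
stops opening new ramifications and reports only the levels that were fully
enumerated (taking the minimum such level across steps): everything lost to
the cap carries at least as many edits as anything reported. On random
genomes the cap is rarely reached; it bites on low-complexity repeats, where
truncation is the intended behaviour.

### N handling

N in a read never matches any reference base, so crossing it always costs
one edit (typically a mismatch; indel placements at the N are also explored
so that completeness is preserved). Reads with more than `max_read_ns`
(default 2) N bases are reported unmapped by policy. N in the *reference* is
replaced at build time by a seeded random base, recorded in a mask on the
index — this keeps the four-letter alphabet exact; reference stretches of Ns
should not be treated as mappable in any case.

## The oracle and the simulator

`brute_force_map` is the independent ground truth: a vectorized
dynamic-programming scan computing, for every reference start `s`, the
minimum edits over all anchored alignments of the read at `s` (free end;
leading read-deletions charged via an explicit anchor combination; the
insertion recurrence along the reference is resolved with a min-plus suffix
scan, so the whole table is `O(L)` numpy passes). `enumerate_edit_scripts`
is a second, exponential oracle that lists every distinct (position, edit
list) alignment without any pruning rules — used to validate the DP and to
count the redundant placements that the shrink gate collapses.

`generate_reference` draws uniform ACGT; `generate_reads` emulates a
dwgsim-style simulation: uniform sampling, per-base mutation rate 0.001,
10% of mutations indels (insertion/deletion equiprobable), constant high
qualities, at most 2 Ns per read (N injection off by default), and a truth
table holding each read's origin and injected edits in the mapper's own
edit grammar. The simulator does not model position-dependent Illumina
error profiles, quality-correlated errors, coverage bias or paired ends;
passing tests therefore demonstrate algorithmic correctness of the search
against the stated edit model, not robustness to platform-specific
artefacts.

## Verification scale and numerical choices

The equivalence suite runs 200 random instances (references 1–5 kb, reads
30–100 bp, `e <= 3`, `segsize = 7` so four segments fit a 30 bp read,
unlimited stack) comparing `search_complete`, `search_prototype` and the DP
oracle; location sets agree exactly, and for `e <= 2` no (position,
edit-list) pair is emitted twice. These sizes keep the whole suite under a
minute while exercising every code path, including direction changes
(`e >= 2`) and all three edit types; development stress testing additionally
covered tandem repeats, homopolymer-rich references and N-containing reads.

Deterministic tie-breaks throughout: mappings sort by (errors, position,
edit list); branch generation visits D, then per base M before I; all
randomness flows through explicitly seeded `numpy` generators. The
branching-factor instrument counts one child per consumed symbol plus one
per surviving ramification, and one parent per state that produced children
— an errorless search measures exactly 1.0, and an unpruned tree would
branch 9 ways (match, four mismatches, four insertions) per position.

`segsize` is user-set; `estimate_segsize` offers a heuristic — the smallest
probe length at which the mean occurrence count of random reference
substrings settles at its final value — reflecting that the useful minimum
is a property of the genome's repeat structure (tens of symbols for
megabase-scale genomes), not a formula.

## Known limitations

* Pure-Python inner loop: throughput is suited to method validation and
  small genomes, not production human-genome mapping.
* No quality-aware scoring or affine gap penalties; all edits cost 1.
* Paired-end reads, BAM/CRAM output, and seed hand-off to a local aligner
  are out of scope; the SAM writer emits a minimal dialect (mandatory
  columns plus `NM`).
* Multi-record references are concatenated with a boundary table; hits
  spanning record boundaries are discarded at reporting time.
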