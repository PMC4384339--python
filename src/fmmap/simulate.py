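"""Ground-truth brute force and synthetic data generation.

``brute_force_map`` is the independent oracle for the tree search: a
dynamic-programming scan that, for every reference start position, finds the
minimum number of edits (mismatches, read-base deletions, reference-base
insertions) needed to align the whole read there. Alignments are anchored the
same way the mapper anchors them: the first reference base of a hit is
consumed by a match or mismatch (leading read deletions are allowed and
charged), and the alignment ends when the read is consumed, so trailing
reference bases are never charged.

``generate_reference``/``generate_reads`` emulate a dwgsim-style simulation:
reads sampled uniformly from a synthetic genome with a per-base mutation
rate (default 0.1%), a fraction of mutations being indels (default 10%,
insertion/deletion equiprobable) and constant high qualities. A truth table
records each read's origin and injected edits in the mapper's edit grammar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import EditOp, canonical_edits, format_edits

_BASES = "ACGT"
BIG = 1 << 20


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def edit_distance_scan(reference: str, W: str) -> np.ndarray:
    """Minimum edits to map the read at each reference start position.

    Returns an array ``h`` of length ``len(reference)``: ``h[s]`` is the
    minimum edit count over all anchored alignments of ``W`` starting at
    ``s``. Vectorized over reference positions; the insertion recurrence
    (a running dependency along the reference) is resolved with a min-plus
    suffix scan per read row.
    """
    X = _codes(reference.upper())
    Wc = _codes(W.upper())
    n, L = X.size, Wc.size
    if L == 0:
        raise ValueError("empty read")
    idx = np.arange(n + 1, dtype=np.int64)
    # g[i][j]: min edits aligning W[i:] with an alignment whose next
    # reference base is X[j]; free end at i == L. Rows kept for the anchored
    # combination below.
    g = np.empty((L + 1, n + 1), dtype=np.int64)
    g[L] = 0
    for i in range(L - 1, -1, -1):
        sub = np.where(X == Wc[i], 0, 1)  # N in the read never matches
        ext = np.full(n + 1, BIG, dtype=np.int64)
        ext[:n] = np.minimum(g[i + 1][1:] + sub, g[i + 1][:n] + 1)
        ext[n] = L - i  # reference exhausted: delete the remaining read
        vals = ext + idx
        suffix_min = np.minimum.accumulate(vals[::-1])[::-1]
        g[i] = suffix_min - idx
    # anchor: k leading read deletions, then W[k] consumes X[s]
    h = np.full(n, BIG, dtype=np.int64)
    for k in range(L):
        sub = np.where(X == Wc[k], 0, 1)
        h = np.minimum(h, k + sub + g[k + 1][1:])
    return h


def brute_force_map(reference: str, W: str, e: int) -> set[tuple[int, int]]:
    """All (position, minimum edit count) pairs reachable within ``e`` edits."""
    h = edit_distance_scan(reference, W)
    return {(int(s), int(h[s])) for s in np.flatnonzero(h <= e)}


def enumerate_edit_scripts(
    reference: str,
    W: str,
    e: int,
    start: int | None = None,
    kinds: str = "DIM",
) -> set[tuple[int, tuple]]:
    """Unpruned enumeration of every distinct (position, edit list) alignment
    within ``e`` edits — exponential; small instances only.

    No redundancy rules are applied, so runs of equal bases yield one result
    per equivalent edit placement (e.g. deleting any G of a homopolymer run).
    ``kinds`` restricts the edit types explored. Insertions are recorded at
    the read position following the inserted base and are not allowed before
    the first (mis)matched read base, mirroring how hits are anchored.
    """
    X = reference.upper()
    Wu = W.upper()
    n, L = len(X), len(Wu)
    results: set[tuple[int, tuple]] = set()
    starts = range(n) if start is None else [start]

    def rec(i: int, j: int, s: int, ops: list, anchored: bool):
        if len(ops) > e:
            return
        if i == L:
            results.add((s, canonical_edits(ops)))
            return
        if j < n:
            if Wu[i] == X[j]:
                rec(i + 1, j + 1, s, ops, True)
            elif "M" in kinds:
                ops.append(EditOp("M", i, _BASES.index(X[j]) + 1))
                rec(i + 1, j + 1, s, ops, True)
                ops.pop()
            if anchored and "I" in kinds:
                ops.append(EditOp("I", i, _BASES.index(X[j]) + 1))
                rec(i, j + 1, s, ops, True)
                ops.pop()
        if "D" in kinds:
            ops.append(EditOp("D", i, 0))
            rec(i + 1, j, s, ops, anchored)
            ops.pop()

    for s in starts:
        rec(0, s, s, [], False)
    return results


@dataclass
class SimParams:
    """dwgsim-style simulation settings: per-base mutation rate, fraction of
    mutations that are indels (insertion/deletion equiprobable), optional N
    masking and the per-read N cap."""

    n_reads: int = 100
    read_length: int = 100
    mutation_rate: float = 0.001
    indel_fraction: float = 0.10
    n_rate: float = 0.0
    max_ns: int = 2
    seed: int = 0
    both_strands: bool = False

    def __post_init__(self):
        for name in ("mutation_rate", "indel_fraction", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be >= 1")


@dataclass
class TrueRead:
    read_id: str
    sequence: str
    position: int
    strand: str
    edits: tuple  # canonical (pos, kind, base_code) triples
    quality: str = ""

    @property
    def n_errors(self) -> int:
        return len(self.edits)

    @property
    def edit_string(self) -> str:
        return format_edits(self.edits)


def generate_reference(length: int, seed: int = 0) -> str:
    """Uniform random ACGT string, deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(_BASES[b] for b in rng.integers(0, 4, size=length))


def generate_reads(reference: str, params: SimParams) -> list[TrueRead]:
    """Sample reads uniformly and inject mutations per the stated rates.

    Each read records its origin position (0-based, forward strand) and the
    injected edits in the mapper's convention: a read-insertion is a D (the
    extra read base must be skipped), a reference-base drop is an I, a
    substitution is an M carrying the original reference base.
    """
    rng = np.random.default_rng(params.seed)
    X = reference.upper()
    n, L = len(X), params.read_length
    slack = max(8, int(L * 0.05))
    if L + slack > n:
        raise ValueError("read length (plus indel slack) exceeds the reference")
    from .tree import revcomp  # local import to avoid a cycle at module load

    reads = []
    for k in range(params.n_reads):
        start = int(rng.integers(0, n - L - slack + 1))
        seq: list[str] = []
        ops: list[EditOp] = []
        i, j = 0, start
        while i < L:
            if rng.random() < params.mutation_rate:
                if rng.random() < params.indel_fraction:
                    if rng.random() < 0.5:  # extra base in the read
                        seq.append(_BASES[rng.integers(4)])
                        ops.append(EditOp("D", i, 0))
                        i += 1
                    else:  # reference base dropped from the read
                        ops.append(EditOp("I", i, _BASES.index(X[j]) + 1))
                        j += 1
                else:
                    b = _BASES[(_BASES.index(X[j]) + int(rng.integers(1, 4))) % 4]
                    seq.append(b)
                    ops.append(EditOp("M", i, _BASES.index(X[j]) + 1))
                    i += 1
                    j += 1
            else:
                seq.append(X[j])
                i += 1
                j += 1
        if params.n_rate > 0:
            n_budget = params.max_ns
            for i in range(L):
                if n_budget and seq[i] != "N" and rng.random() < params.n_rate:
                    seq[i] = "N"
                    n_budget -= 1
        strand = "+"
        sequence = "".join(seq)
        if params.both_strands and rng.random() < 0.5:
            strand = "-"
            sequence = revcomp(sequence)
        reads.append(
            TrueRead(
                read_id=f"sim_{k}",
                sequence=sequence,
                position=start,
                strand=strand,
                edits=canonical_edits(ops),
                quality="I" * L,
            )
        )
    return reads
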