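"""Pruned search-tree exploration: lossless inexact mapping on an FM-index.

Given a maximum error budget ``e``, the search returns every reference
location where the read aligns with at most ``e`` edits (mismatches,
insertions of reference bases, deletions of read bases). Exponential tree
growth is controlled by four pruning devices, none of which sacrifices a
mapping:

* dead branches (``k > l``) are discarded;
* error branches are only opened where the interval shrinks
  (``res' < res``): if extending with the read's own symbol loses no
  occurrences, every alternative either dies immediately or is a relabelling
  of an alignment reachable elsewhere, so the position is skipped;
* pairs of consecutive edits that are equivalent to a single cheaper edit
  (I-D, D-I and base-dependent I/M, M/I, D/M, M/D combinations) are refused;
* a per-position lower bound ``D`` on the edits still required (built from
  disjoint read windows that are not reference substrings) cuts partial
  results whose budget cannot suffice.

Two drivers are provided. ``search_prototype`` explores the whole read in a
single backward pass — simple, correct, slow when the interval is still wide.
``search_complete`` divides the read into ``e+1`` segments and runs ``e+1``
steps; each step exact-matches its designated segment first (so the interval
is narrow before any error branch opens), then extends leftwards over the
earlier segments — each of which must then contain at least one error, which
partitions the error placements exactly across steps — changes direction
once, and finishes rightwards.

Edit-operation conventions: a deletion (D) skips a read base without a
search iteration; an insertion I(b) consumes reference base ``b`` without
advancing in the read; a mismatch M(b) consumes reference base ``b`` and
advances. Insertions are recorded at the read position *following* the
inserted base regardless of search direction, so the same physical alignment
receives the same edit list whichever step discovers it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .index import _CHAR, _CODE, FMIndex
from .search import EMPTY, SAInterval, fm_iteration, initial_interval

logger = logging.getLogger("fmmap")

N_CODE = 5
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "EditOp",
    "SearchConfig",
    "Mapping",
    "PartialResult",
    "ResultList",
    "is_pair_allowed",
    "detect_branch_points",
    "compute_D",
    "change_direction",
    "search_prototype",
    "search_complete",
    "map_read",
    "max_errors_for",
    "estimate_segsize",
    "measure_branching_factor",
    "revcomp",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class EditOp(NamedTuple):
    """One edit: kind 'D' | 'I' | 'M'; read position; reference base code
    (0 for D). ``phys`` orders same-position insertions left-to-right and is
    ignored when comparing edit lists."""

    kind: str
    pos: int
    base: int
    phys: int = 0


def canonical_edits(errors: Iterable[EditOp]) -> tuple:
    """Direction-independent form of an edit list: sorted by read position
    (physical sub-order for same-junction insertions), phys stripped."""
    ordered = sorted(errors, key=lambda op: (op.pos, op.phys))
    return tuple((op.pos, op.kind, op.base) for op in ordered)


def format_edits(canon: tuple) -> str:
    """Compact ``pos:kind(base)`` grammar, e.g. ``4:M(G),7:D``."""
    parts = []
    for pos, kind, base in canon:
        parts.append(f"{pos}:{kind}" if kind == "D" else f"{pos}:{kind}({_CHAR[base]})")
    return ",".join(parts) if parts else "."


@dataclass(frozen=True)
class Mapping:
    """A final answer: 0-based reference position, strand, canonical edits."""

    read_id: str
    position: int
    strand: str
    edits: tuple  # canonical (pos, kind, base_code) triples
    ref_span: int  # reference bases covered

    @property
    def n_errors(self) -> int:
        return len(self.edits)

    @property
    def edit_string(self) -> str:
        return format_edits(self.edits)


@dataclass
class SearchConfig:
    """Tunable knobs of the inexact search.

    ``max_errors``      edit budget e (>= 0)
    ``segsize``         minimum exact-segment length; (e+1)*segsize must fit
                        in the read or e is lowered
    ``stack_limit``     capacity of the partial-result lists; on overflow the
                        highest-error (then least-advanced) results are shed
    ``traversal``       'hybrid' (BFS until the last ramification, then DFS)
                        or 'bfs'
    ``max_read_ns``     reads with more N bases than this are not mapped
    ``use_d_vector``    enable the lower-bound pruning
    ``pair_rules``      enable consecutive-edit deduplication rules
    """

    max_errors: int = 0
    segsize: int = 15
    stack_limit: int = 50_000
    traversal: str = "hybrid"
    max_read_ns: int = 2
    use_d_vector: bool = True
    pair_rules: bool = True
    dedup_positions: bool = False

    def __post_init__(self):
        if self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")
        if self.segsize < 1:
            raise ValueError("segsize must be >= 1")
        if self.traversal not in ("hybrid", "bfs"):
            raise ValueError("traversal must be 'hybrid' or 'bfs'")


def max_errors_for(read_length: int, segsize: int) -> int:
    """Largest budget with e+1 exact segments of at least segsize symbols."""
    return max(read_length // segsize - 1, 0)


class _Block(NamedTuple):
    lo: int
    hi: int
    backward: bool
    inexact: bool
    must_have_error: bool


class PartialResult:
    """An in-progress search state: interval, next read position, schedule
    block, accumulated edits and pair-rule context."""

    __slots__ = (
        "interval",
        "position",
        "block",
        "errors",
        "last_op",
        "gap",
        "ref_len",
        "analysed",
    )

    def __init__(self, interval: SAInterval, position: int, block: int = 0):
        self.interval = interval
        self.position = position
        self.block = block
        self.errors: tuple = ()
        self.last_op: EditOp | None = None
        self.gap = True  # a match separates us from the last edit
        self.ref_len = 0
        self.analysed = 0

    def clone(self) -> "PartialResult":
        c = PartialResult.__new__(PartialResult)
        c.interval = self.interval
        c.position = self.position
        c.block = self.block
        c.errors = self.errors
        c.last_op = self.last_op
        c.gap = self.gap
        c.ref_len = self.ref_len
        c.analysed = self.analysed
        return c

    def __repr__(self):  # pragma: no cover - debugging aid
        return (
            f"PartialResult([{self.interval.k},{self.interval.l}] at "
            f"{self.position} with {list(self.errors)})"
        )


class ResultList:
    """Bounded partial-result list. When full, the result with the most
    errors (ties: fewest analysed symbols) is shed first, so a small stack
    retains the best candidate alignments."""

    __slots__ = ("capacity", "items", "overflowed")

    def __init__(self, capacity: int | None = None):
        self.capacity = capacity
        self.items: list[PartialResult] = []
        self.overflowed = False

    def __len__(self):
        return len(self.items)

    @staticmethod
    def _badness(r: PartialResult) -> tuple:
        return (len(r.errors), -r.analysed)

    def add(self, r: PartialResult) -> None:
        if self.capacity is None or len(self.items) < self.capacity:
            self.items.append(r)
            return
        self.overflowed = True
        worst_i = max(range(len(self.items)), key=lambda i: self._badness(self.items[i]))
        if self._badness(r) < self._badness(self.items[worst_i]):
            self.items[worst_i] = r


def _encode_read(W: str) -> list[int]:
    codes = []
    for c in W.upper():
        if c == "N":
            codes.append(N_CODE)
        else:
            try:
                codes.append(_CODE[c])
            except KeyError:
                raise ValueError(f"read symbol {c!r} outside ACGTN") from None
    return codes


# ---------------------------------------------------------------------------
# Pair rules for consecutive edits
# ---------------------------------------------------------------------------

def is_pair_allowed(
    prev: EditOp | None, nxt: EditOp, read_codes, fold_budget: int | None = None
) -> bool:
    """Whether edit ``nxt`` may immediately follow ``prev`` (no match in
    between). The forbidden pairs are exactly those equivalent to a single
    cheaper edit, in either search direction:

    * an insertion next to a deletion (either order) is a mismatch;
    * a deletion next to a mismatch whose base equals the deleted read base
      re-labels a single deletion;
    * an insertion next to a mismatch at the insertion's base re-labels a
      single insertion.

    One exception: when a backward scan reaches the left edge, folding an
    I-then-M pair would turn it into an insertion *before* the first aligned
    read base — an alignment anchored one position later, at a different
    mapping position — so the pair must be kept. ``fold_budget`` (the edits
    still affordable after ``nxt``) bounds how deep that edge zone reaches:
    the fold is only un-anchored if every read base left of the mismatch
    could still be deleted.
    """
    if prev is None:
        return True
    a, b = prev.kind, nxt.kind
    if a == "M" and b == "M":
        return True
    if ("I" in (a, b)) and ("D" in (a, b)):
        return False
    if a == "D" and b == "M":
        return nxt.base != read_codes[prev.pos]
    if a == "M" and b == "D":
        return prev.base != read_codes[nxt.pos]
    if a == "I" and b == "M":
        if (
            prev.pos == nxt.pos + 1
            and fold_budget is not None
            and nxt.pos <= fold_budget
        ):
            return True  # fold target would be a leading insertion
        return prev.base != read_codes[nxt.pos]
    if a == "M" and b == "I":
        return nxt.base != read_codes[prev.pos]
    return True  # I-I, D-D


# ---------------------------------------------------------------------------
# Branch-point diagnostic
# ---------------------------------------------------------------------------

def detect_branch_points(
    index: FMIndex, W: str, direction: str = "forward", span: tuple | None = None
) -> list[int]:
    """Read positions where the occurrence count ``res`` strictly shrinks
    between consecutive non-empty prefixes of the scan.

    The first analysed symbol sets the baseline (the drop from the
    sentinel-inclusive initial interval is not a branch point here); the scan
    stops after the first empty interval, which is itself reported.
    """
    codes = _encode_read(W)
    lo, hi = span if span is not None else (0, len(codes) - 1)
    if direction == "forward":
        side, order = index.rev, range(lo, hi + 1)
    elif direction == "backward":
        side, order = index.fwd, range(hi, lo - 1, -1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    iv = initial_interval(side)
    prev_res = None
    points = []
    for i in order:
        nxt = fm_iteration(side, iv, codes[i]) if codes[i] != N_CODE else EMPTY
        if prev_res is not None and nxt.res < prev_res:
            points.append(i)
        if nxt.empty:
            break
        prev_res = nxt.res
        iv = nxt
    return points


# ---------------------------------------------------------------------------
# D vector: lower bound on the edits still needed
# ---------------------------------------------------------------------------

def compute_D(
    index: FMIndex, W: str | list[int], start: int, end: int, direction: str
) -> np.ndarray:
    """Per-position lower bound on the edits needed to map the read region
    that remains when the scan stands at that position.

    The exact segment [start, end] is zero. For ``direction='backward'``,
    D[i] (i < start) bounds the edits in W[0..i]: scanning i upwards, a
    window grows by forward extension and every time it stops being a
    reference substring one error is charged and the window restarts —
    disjoint non-substring windows each force an edit in any alignment, so
    the bound is admissible and pruning with it is lossless. The forward
    direction mirrors this for W[i..L-1], i > end, with backward extension.
    N bases never match and charge an edit immediately.
    """
    codes = _encode_read(W) if isinstance(W, str) else W
    L = len(codes)
    D = np.zeros(L, dtype=np.int64)
    if direction == "backward":
        side = index.rev
        iv = initial_interval(side)
        z = 0
        for i in range(0, start):
            nxt = fm_iteration(side, iv, codes[i]) if codes[i] != N_CODE else EMPTY
            if nxt.empty:
                z += 1
                iv = initial_interval(side)
            else:
                iv = nxt
            D[i] = z
    elif direction == "forward":
        side = index.fwd
        iv = initial_interval(side)
        z = 0
        for i in range(L - 1, end, -1):
            nxt = fm_iteration(side, iv, codes[i]) if codes[i] != N_CODE else EMPTY
            if nxt.empty:
                z += 1
                iv = initial_interval(side)
            else:
                iv = nxt
            D[i] = z
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return D


# ---------------------------------------------------------------------------
# Direction change
# ---------------------------------------------------------------------------

def change_direction(
    index: FMIndex, interval: SAInterval, match_length: int, backward: bool
) -> SAInterval:
    """Re-express an interval in the opposite index.

    Every rank is located, its start mapped through the reversal coordinate
    map (start' = n - 1 - start - match_length) and re-ranked with the other
    side's inverse SA. The located set is unchanged and, as the interval of
    the reversed matched string, the image is contiguous. Interval sizes at a
    direction change are small in practice, so the per-rank work is cheap.
    """
    # the old direction is the opposite of ``backward``; a backward scan uses
    # the forward text's index and vice versa
    src = index.side(backward)
    dst = index.side(not backward)
    n = index.n
    ranks = []
    for rank in range(interval.k, interval.l + 1):
        p = src.sa(rank)
        ranks.append(dst.isa(n - 1 - p - match_length))
    lo, hi = min(ranks), max(ranks)
    if hi - lo + 1 != len(ranks):  # pragma: no cover - structural invariant
        raise AssertionError("direction change produced a non-contiguous interval")
    return SAInterval(lo, hi)


# ---------------------------------------------------------------------------
# The exploration engine
# ---------------------------------------------------------------------------

class _Engine:
    """Runs one schedule (a sequence of blocks) over one read."""

    def __init__(
        self,
        index: FMIndex,
        codes: list[int],
        schedule: list[_Block],
        e: int,
        config: SearchConfig,
        d_vectors: dict | None,
        counters: dict | None = None,
    ):
        self.index = index
        self.codes = codes
        self.schedule = schedule
        self.e = e
        self.config = config
        self.d_vectors = d_vectors or {}
        self.counters = counters
        self.finals: list[PartialResult] = []
        self.overflowed = False
        self.complete_through: int | None = None  # None = fully explored

    def run(self, seed: PartialResult) -> list[PartialResult]:
        """Level-ordered exploration: round j holds partial results with
        exactly j edits, so finals with j edits are all collected before any
        deeper ramification opens. When a bounded list overflows, exploration
        stops and ``complete_through`` records the last fully explored level;
        the caller discards deeper (incomplete) finals so that everything
        lost to the cap carries at least as many edits as anything kept."""
        cap = self.config.stack_limit
        rl_p = ResultList(cap)
        rl_p.add(seed)
        level = 0
        while rl_p.items:
            rl_n = ResultList(cap)
            for r in rl_p.items:
                self._exact(r, rl_n)
            rl_p = ResultList(cap)
            for cand in rl_n.items:
                self._branch(cand, rl_p)
            if rl_n.overflowed or rl_p.overflowed:
                self.overflowed = True
                self.complete_through = level
                break
            level += 1
        return self.finals

    # -- exact phase -------------------------------------------------------

    def _exact(self, r: PartialResult, rl_n: ResultList) -> None:
        """Advance ``r`` with exact extensions until it finishes, dies, or is
        pruned; emit a branch candidate at every res' < res position."""
        codes = self.codes
        schedule = self.schedule
        e = self.e
        counters = self.counters
        while True:
            if r.block >= len(schedule):
                self.finals.append(r)
                return
            blk = schedule[r.block]
            pos = r.position
            if (pos < blk.lo) if blk.backward else (pos > blk.hi):
                # block completed
                if blk.must_have_error and not any(
                    blk.lo <= op.pos <= blk.hi for op in r.errors
                ):
                    return
                nb = r.block + 1
                if nb < len(schedule) and schedule[nb].backward != blk.backward:
                    r.interval = change_direction(
                        self.index, r.interval, r.ref_len, schedule[nb].backward
                    )
                    r.position = schedule[nb].hi if schedule[nb].backward else schedule[nb].lo
                    r.gap = True
                r.block = nb
                continue
            if blk.inexact and self.d_vectors:
                D = self.d_vectors["backward" if blk.backward else "forward"]
                if len(r.errors) + D[pos] > e:
                    return
            side = self.index.side(not blk.backward)
            a = codes[pos]
            nxt = fm_iteration(side, r.interval, a) if a != N_CODE else EMPTY
            if blk.inexact and len(r.errors) < e:
                # branch where occurrences are lost -- and always inside the
                # left-edge zone, where an indel in a run touching the read
                # start shifts the mapping position and would otherwise only
                # surface at the shifted start with fewer errors
                if nxt.res < r.interval.res or (
                    blk.backward and pos + len(r.errors) < e
                ):
                    rl_n.add(r.clone())
            if nxt.empty:
                return
            if counters is not None:
                counters["branches"] = counters.get("branches", 0) + 1
                counters["parents"] = counters.get("parents", 0) + 1
            r.interval = nxt
            r.ref_len += 1
            r.analysed += 1
            r.gap = True
            r.position = pos - 1 if blk.backward else pos + 1

    # -- branch phase ------------------------------------------------------

    def _branch(self, cand: PartialResult, rl_p: ResultList) -> None:
        """Open D, I(b) and M(b) ramifications at the candidate's position."""
        codes = self.codes
        blk = self.schedule[cand.block]
        backward = blk.backward
        step = -1 if backward else 1
        p = cand.position
        prev = None if cand.gap else cand.last_op
        side = self.index.side(not backward)
        rules = self.config.pair_rules
        hybrid = self.config.traversal == "hybrid"
        nerr = len(cand.errors)
        gen = nerr + 1
        fold_budget = self.e - nerr - 1
        children = 0

        def emit(child: PartialResult) -> None:
            nonlocal children
            children += 1
            if hybrid and len(child.errors) == self.e:
                # last ramification: no further branching possible, finish
                # this line depth-first instead of queueing it
                self._exact(child, _NULL_LIST)
            else:
                rl_p.add(child)

        # deletion: skip the read base, no reference consumed
        op = EditOp("D", p, 0, gen if not backward else -gen)
        if (not rules) or is_pair_allowed(prev, op, codes, fold_budget):
            child = cand.clone()
            child.position = p + step
            child.errors = cand.errors + (op,)
            child.last_op = op
            child.gap = False
            child.analysed += 1
            emit(child)

        a = codes[p]
        ins_pos = p + 1 if backward else p  # junction before the next unmatched base
        for b in (1, 2, 3, 4):
            nxt = fm_iteration(side, cand.interval, b)
            if nxt.empty:
                continue
            if b != a:
                op = EditOp("M", p, b, gen if not backward else -gen)
                if (not rules) or is_pair_allowed(prev, op, codes, fold_budget):
                    child = cand.clone()
                    child.interval = nxt
                    child.position = p + step
                    child.errors = cand.errors + (op,)
                    child.last_op = op
                    child.gap = False
                    child.ref_len += 1
                    child.analysed += 1
                    emit(child)
            op = EditOp("I", ins_pos, b, gen if not backward else -gen)
            if (not rules) or is_pair_allowed(prev, op, codes, fold_budget):
                child = cand.clone()
                child.interval = nxt
                child.errors = cand.errors + (op,)
                child.last_op = op
                child.gap = False
                child.ref_len += 1
                emit(child)

        if self.counters is not None and children:
            self.counters["branches"] = self.counters.get("branches", 0) + children
            self.counters["parents"] = self.counters.get("parents", 0) + 1


class _NullList:
    """Sink for the DFS fast path: a budget-exhausted child can emit no
    further branch candidates."""

    def add(self, r):  # pragma: no cover - structural guard
        raise AssertionError("exhausted result tried to branch")


_NULL_LIST = _NullList()


# ---------------------------------------------------------------------------
# Mapping assembly
# ---------------------------------------------------------------------------

def _collect(
    index: FMIndex,
    finals: list[PartialResult],
    last_backward: bool,
    read_id: str,
    strand: str,
    config: SearchConfig,
    out: dict,
    counters: dict | None = None,
) -> None:
    side = index.side(not last_backward)
    n = index.n
    for r in finals:
        canon = canonical_edits(r.errors)
        for rank in range(r.interval.k, r.interval.l + 1):
            p = side.sa(rank)
            start = p if last_backward else n - 1 - p - r.ref_len
            if counters is not None:
                counters["raw_mappings"] = counters.get("raw_mappings", 0) + 1
                if (start, canon) in out:
                    counters["duplicates"] = counters.get("duplicates", 0) + 1
            key = (start,) if config.dedup_positions else (start, canon)
            if key not in out or len(canon) < out[key].n_errors:
                out[key] = Mapping(read_id, start, strand, canon, r.ref_len)


def search_prototype(
    index: FMIndex,
    W: str,
    e: int,
    config: SearchConfig | None = None,
    read_id: str = "read",
    strand: str = "+",
    counters: dict | None = None,
) -> list[Mapping]:
    """Single-pass inexact search: one backward scan of the whole read with
    error branches opened wherever the interval shrinks. Lossless but slow
    while the interval is wide; the segment-stepped ``search_complete`` is
    the production driver."""
    config = config or SearchConfig(max_errors=e)
    codes = _encode_read(W)
    L = len(codes)
    schedule = [_Block(0, L - 1, True, True, False)]
    engine = _Engine(index, codes, schedule, e, config, None, counters)
    seed = PartialResult(initial_interval(index.fwd), L - 1)
    finals = engine.run(seed)
    out: dict = {}
    _collect(index, finals, True, read_id, strand, config, out, counters)
    mappings = out.values()
    if engine.complete_through is not None:
        logger.info(
            "read %s: stack limit hit, results truncated at %d error(s)",
            read_id, engine.complete_through,
        )
        mappings = [m for m in mappings if m.n_errors <= engine.complete_through]
    return sorted(mappings, key=lambda m: (m.n_errors, m.position, m.edits))


def _segments(L: int, e: int) -> list[tuple[int, int]]:
    """Split [0, L) into e+1 near-equal contiguous segments."""
    bounds = [round(i * L / (e + 1)) for i in range(e + 2)]
    return [(bounds[i], bounds[i + 1] - 1) for i in range(e + 1)]


def search_complete(
    index: FMIndex,
    W: str,
    config: SearchConfig,
    read_id: str = "read",
    strand: str = "+",
    counters: dict | None = None,
) -> list[Mapping]:
    """Segment-stepped lossless inexact search (the production driver).

    The read is split into ``e+1`` segments; step ``s`` exact-matches
    segment ``s`` (skipping the step when it is absent from the reference),
    extends leftwards over segments ``s-1 .. 0`` — each of which must gain at
    least one error, because placements leaving it exact were already covered
    by the earlier step that seeded it — then changes direction and extends
    rightwards to the read end. The union over steps is exactly the set of
    <= e-error mappings.
    """
    codes = _encode_read(W)
    L = len(codes)
    e = config.max_errors
    if L < config.segsize:
        warnings.warn(
            f"read shorter than segsize ({L} < {config.segsize}); "
            "falling back to the single-pass search"
        )
        return search_prototype(index, W, e, config, read_id, strand, counters)
    emax = max_errors_for(L, config.segsize)
    if e > emax:
        warnings.warn(
            f"(e+1)*segsize exceeds the read length; lowering e from {e} to {emax}"
        )
        e = emax
    segs = _segments(L, e)
    out: dict = {}
    complete_through: int | None = None
    for s in range(e + 1):
        lo_s, hi_s = segs[s]
        schedule: list[_Block] = []
        if s == 0:
            schedule.append(_Block(lo_s, hi_s, False, False, False))
            if hi_s < L - 1:
                schedule.append(_Block(hi_s + 1, L - 1, False, True, False))
            seed = PartialResult(initial_interval(index.rev), lo_s)
            last_backward = False
        else:
            schedule.append(_Block(lo_s, hi_s, True, False, False))
            for j in range(s - 1, -1, -1):
                schedule.append(_Block(segs[j][0], segs[j][1], True, True, True))
            if hi_s < L - 1:
                schedule.append(_Block(hi_s + 1, L - 1, False, True, False))
                last_backward = False
            else:
                last_backward = True
            seed = PartialResult(initial_interval(index.fwd), hi_s)
        d_vectors = None
        if config.use_d_vector and e > 0:
            d_vectors = {
                "backward": compute_D(index, codes, lo_s, hi_s, "backward"),
                "forward": compute_D(index, codes, lo_s, hi_s, "forward"),
            }
        engine = _Engine(index, codes, schedule, e, config, d_vectors, counters)
        finals = engine.run(seed)
        _collect(index, finals, last_backward, read_id, strand, config, out, counters)
        if engine.complete_through is not None and (
            complete_through is None or engine.complete_through < complete_through
        ):
            complete_through = engine.complete_through
    mappings = out.values()
    if complete_through is not None:
        # a step hit the stack limit: levels above its last complete one are
        # only partially enumerated, so keep the guaranteed-complete ones
        logger.info(
            "read %s: stack limit hit, results truncated at %d error(s)",
            read_id, complete_through,
        )
        mappings = [m for m in mappings if m.n_errors <= complete_through]
    return sorted(mappings, key=lambda m: (m.n_errors, m.position, m.edits))


def map_read(
    index: FMIndex,
    read_id: str,
    seq: str,
    config: SearchConfig,
    rc: bool = False,
) -> list[Mapping]:
    """Map one read: N-count policy, forward (and optionally reverse
    complement) search, record-boundary filtering."""
    seq = seq.upper()
    if seq.count("N") > config.max_read_ns:
        logger.info("read %s skipped: more than %d N bases", read_id, config.max_read_ns)
        return []
    mappings = search_complete(index, seq, config, read_id, "+")
    if rc:
        mappings += search_complete(index, revcomp(seq), config, read_id, "-")
    kept = [
        m for m in mappings if index.record_at(m.position, m.ref_span) is not None
    ]
    return sorted(kept, key=lambda m: (m.n_errors, m.position, m.strand, m.edits))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def measure_branching_factor(
    index: FMIndex, reads: Iterable[str], config: SearchConfig
) -> float:
    """Average branching factor: total branches over nodes with descendants,
    aggregated across the given reads. Exact extension contributes one child
    per consumed symbol; every surviving ramification at a branch point is a
    further child of its node. An errorless search is a chain (factor 1.0);
    an unpruned tree over match, mismatches and insertions would branch 9
    ways per node."""
    counters: dict = {}
    for W in reads:
        search_complete(index, W, config, counters=counters)
    if not counters.get("parents"):
        return 0.0
    return counters["branches"] / counters["parents"]


def estimate_segsize(
    index: FMIndex,
    probes: int = 200,
    max_len: int = 40,
    seed: int = 0,
    tolerance: float = 0.5,
) -> int:
    """Heuristic minimum segment length: the smallest probe length at which
    the mean occurrence count of random reference substrings has settled at
    its final value (within ``tolerance``), i.e. where the res' < res pruning
    becomes informative."""
    rng = np.random.default_rng(seed)
    n_text = index.n - 1
    max_len = min(max_len, n_text)
    means = np.zeros(max_len)
    side = index.fwd
    starts = rng.integers(0, n_text - max_len + 1, size=probes)
    # probe symbols are read off the index itself: text[p] = B[R[p+1]]
    for p in starts:
        iv = initial_interval(side)
        for j in range(max_len):
            pos = int(p) + max_len - 1 - j  # extend backward from the right end
            a = int(side.bwt[side.isa(pos + 1)])
            iv = fm_iteration(side, iv, a)
            means[max_len - 1 - j] += iv.res
    means /= probes
    final = means[max_len - 1]
    length = max_len
    for L in range(max_len, 0, -1):
        if abs(means[L - 1] - final) <= tolerance:
            length = L
        else:
            break
    return length
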