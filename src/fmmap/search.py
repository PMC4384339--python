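"""Exact backward search over an FM-index.

Backward search narrows a suffix-array rank interval ``[k, l]`` by
prepending pattern symbols: if ``[k, l]`` covers the occurrences of a string
``V``, one ``search_iteration`` with symbol ``a`` yields the interval of
``a·V``. The interval size ``res = l - k + 1`` is the occurrence count and
can only shrink (``res' <= res``), which the inexact search exploits.

"Forward" search (extending a read left to right) is realized as backward
search of the reversed pattern over the reversed-text index; no bidirectional
index is kept. The iteration function is injectable so another backward
search runtime can stand in for the FM-index one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

from .index import _CODE, FMIndex, FMSide


class SAInterval(NamedTuple):
    """A suffix-array rank interval; non-empty iff k <= l."""

    k: int
    l: int

    @property
    def res(self) -> int:
        """Occurrence count of the current string; 0 when empty."""
        return max(self.l - self.k + 1, 0)

    @property
    def empty(self) -> bool:
        return self.k > self.l


EMPTY = SAInterval(0, -1)


def initial_interval(side: FMSide) -> SAInterval:
    """The whole-SA interval [0, n-1]; the sentinel row is included until
    the first iteration."""
    return SAInterval(0, side.n - 1)


def fm_iteration(side: FMSide, interval: SAInterval, a: int) -> SAInterval:
    """One backward-search step: interval of ``a·V`` from the interval of V.

    With O(a, i) counting ``a`` in B[0:i] and C excluding the sentinel,
    ``k' = C(a) + O(a, k) + 1`` and ``l' = C(a) + O(a, l+1)``; the +1 absorbs
    the sentinel suffix occupying rank 0.
    """
    if not 1 <= a <= 4:
        raise ValueError(f"symbol code {a} outside alphabet")
    if interval.empty:
        return EMPTY
    c = int(side.C[a - 1])
    k = c + side.occtab.occ(a, interval.k) + 1
    l = c + side.occtab.occ(a, interval.l + 1)
    return SAInterval(k, l) if k <= l else EMPTY


IterationFn = Callable[[FMSide, SAInterval, int], SAInterval]


@dataclass
class SearchResult:
    """Outcome of an exact search: final interval, where the scan stopped,
    and the direction it ran in. Exact search carries no edits."""

    interval: SAInterval
    position: int
    direction: str = "backward"  # 'backward' | 'forward'
    errors: list = field(default_factory=list)

    @property
    def found(self) -> bool:
        return not self.interval.empty


def _encode_read(W: str) -> list[int]:
    try:
        return [_CODE[c] for c in W.upper()]
    except KeyError as exc:
        raise ValueError(f"read symbol outside alphabet: {exc}") from exc


def bws(
    index: FMIndex,
    W: str,
    direction: str = "backward",
    iteration: IterationFn = fm_iteration,
) -> SearchResult:
    """Exact search of ``W``; backward scans right-to-left on the forward
    index, forward scans left-to-right on the reversed index.

    If the interval empties, ``position`` records the read index where the
    scan stopped (the symbol that could not be extended); on success it is
    one step past the final symbol (-1 backward, ``len(W)`` forward).
    """
    if not W:
        raise ValueError("empty pattern")
    codes = _encode_read(W)
    if direction == "backward":
        side, order, stop = index.fwd, range(len(codes) - 1, -1, -1), -1
    elif direction == "forward":
        side, order, stop = index.rev, range(len(codes)), len(codes)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    iv = initial_interval(side)
    for i in order:
        nxt = iteration(side, iv, codes[i])
        if nxt.empty:
            return SearchResult(nxt, i, direction)
        iv = nxt
    return SearchResult(iv, stop, direction)


def locate(
    index: FMIndex,
    interval: SAInterval,
    match_length: int,
    direction: str = "backward",
) -> set[int]:
    """Forward-text start positions of all occurrences in the interval.

    Reversed-index hits at reversed position p map to forward start
    ``n - 1 - p - match_length`` (n includes the sentinel).
    """
    if interval.empty:
        return set()
    side = index.side(direction == "forward")
    if not (0 <= interval.k and interval.l < side.n):
        raise IndexError("interval out of range")
    positions = set()
    for rank in range(interval.k, interval.l + 1):
        p = side.sa(rank)
        if direction == "forward":
            p = index.n - 1 - p - match_length
        positions.add(p)
    return positions


def search_and_locate(index: FMIndex, W: str, direction: str = "backward") -> set[int]:
    """Convenience: exact occurrence set of W in the forward text."""
    res = bws(index, W, direction)
    if not res.found:
        return set()
    return locate(index, res.interval, len(W), direction)
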