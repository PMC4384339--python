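"""FM-index construction, compression and rank/locate primitives.

The index holds, for the reference text and for its reverse, the four
structures needed by backward search:

* ``B``   -- the Burrows-Wheeler transform of the sentinel-terminated text,
* ``C``   -- for each base, the number of BWT symbols lexicographically
  smaller than it (the sentinel is excluded from the counts),
* ``O``   -- the occurrence table ``O(a, i)`` = number of ``a`` in
  ``B[0:i]``, stored compressed as per-symbol bit vectors of ``w`` bits
  (``O_count``) plus one running count per vector (``O_disp``),
* ``S``/``R`` -- the suffix array and its inverse, sampled every ``r``
  positions (``Scomp[k] = S[k*r]``, ``Rcomp[k] = R[k*r]``) and reconstructed
  on demand by iterating the LF-step ``psi_inverse``.

Texts are kept as uint8 code arrays over ``$ < A < C < G < T`` (codes 0-4).
The sentinel sorts strictly below every base, which makes the suffix order
unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

INDEX_FORMAT_VERSION = 1

SENTINEL = 0
ALPHABET = "ACGT"
_CODE = {"$": 0, "A": 1, "C": 2, "G": 3, "T": 4}
_CHAR = "$ACGT"

__all__ = [
    "SENTINEL",
    "ALPHABET",
    "encode",
    "decode",
    "build_suffix_array",
    "bwt_from_sa",
    "compute_C",
    "OccTable",
    "compress_occ",
    "occ",
    "CompressedSA",
    "FMSide",
    "FMIndex",
    "build_index",
    "save_index",
    "load_index",
]


def encode(text: str) -> np.ndarray:
    """Map a ``$``-terminated A/C/G/T string to a uint8 code array."""
    try:
        codes = np.frombuffer(
            bytes(_CODE[c] for c in text), dtype=np.uint8
        ).copy()
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"symbol outside alphabet+sentinel: {exc}") from exc
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_CHAR[c] for c in codes)


def _validate_text(codes: np.ndarray) -> None:
    if codes.size == 0:
        raise ValueError("empty text")
    sentinels = np.flatnonzero(codes == SENTINEL)
    if sentinels.size != 1 or sentinels[0] != codes.size - 1:
        raise ValueError("text must contain exactly one sentinel, at the end")
    if codes.max(initial=0) > 4:
        raise ValueError("symbol outside alphabet+sentinel")


def build_suffix_array(text: str | np.ndarray) -> np.ndarray:
    """Suffix array of a sentinel-terminated text by prefix doubling.

    Returns the permutation ``S`` with ``text[S[0]:] < text[S[1]:] < ...``.
    ``O(n log n)`` numpy sorts; comfortably handles megabase references.
    """
    codes = encode(text) if isinstance(text, str) else np.asarray(text, np.uint8)
    _validate_text(codes)
    n = codes.size
    rank = codes.astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        # rank of suffix i+k; suffixes running off the end rank lowest,
        # which the sentinel already guarantees cannot tie with a live one
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        key_prev = (rank[order], second[order])
        new_rank = np.empty(n, dtype=np.int64)
        boundaries = np.ones(n, dtype=np.int64)
        boundaries[1:] = (key_prev[0][1:] != key_prev[0][:-1]) | (
            key_prev[1][1:] != key_prev[1][:-1]
        )
        new_rank[order] = np.cumsum(boundaries) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            sa = order
            break
        k *= 2
    return sa


def bwt_from_sa(text: str | np.ndarray, sa: np.ndarray) -> np.ndarray:
    """BWT as code array: ``B[i] = text[(S[i]-1) mod n]``."""
    codes = encode(text) if isinstance(text, str) else np.asarray(text, np.uint8)
    _validate_text(codes)
    sa = np.asarray(sa)
    if sa.size != codes.size:
        raise ValueError("suffix array length does not match text")
    return codes[(sa - 1) % codes.size]


def compute_C(bwt: np.ndarray | str) -> np.ndarray:
    """Smaller-symbol counts ``C(a)`` over A<C<G<T, sentinel excluded."""
    codes = encode(bwt) if isinstance(bwt, str) else np.asarray(bwt, np.uint8)
    if codes.max(initial=0) > 4:
        raise ValueError("symbol outside alphabet+sentinel")
    counts = np.bincount(codes, minlength=5)[1:5]
    return np.concatenate(([0], np.cumsum(counts)[:-1])).astype(np.int64)


class OccTable:
    """Two-matrix compressed occurrence table.

    For each base, ``words[a]`` is a sequence of ``ceil(n/w)`` w-bit vectors
    (bit j of vector k set iff ``B[k*w + j] == a``; least-significant bit is
    the lowest BWT position) and ``disp[a][k]`` counts occurrences of ``a``
    strictly before position ``k*w``.
    """

    __slots__ = ("w", "n", "words", "disp")

    def __init__(self, w: int, n: int, words: list[list[int]], disp: np.ndarray):
        self.w = w
        self.n = n
        self.words = words
        self.disp = disp

    @classmethod
    def build(cls, bwt: np.ndarray | str, w: int) -> "OccTable":
        if w < 1:
            raise ValueError("word size must be >= 1")
        if w > 64:
            raise ValueError("word size must be <= 64")
        codes = encode(bwt) if isinstance(bwt, str) else np.asarray(bwt, np.uint8)
        n = codes.size
        nwords = (n + w - 1) // w
        words: list[list[int]] = []
        disp = np.zeros((4, nwords), dtype=np.int64)
        for a in range(1, 5):
            hits = codes == a
            row = []
            running = 0
            for k in range(nwords):
                disp[a - 1, k] = running
                block = hits[k * w : (k + 1) * w]
                word = 0
                for j in np.flatnonzero(block):
                    word |= 1 << int(j)
                row.append(word)
                running += int(block.sum())
            words.append(row)
        return cls(w, n, words, disp)

    def occ(self, a: int, i: int) -> int:
        """Occurrences of base code ``a`` (1..4) in ``B[0:i]``."""
        if not 0 <= i <= self.n:
            raise IndexError("occ index out of range")
        if i == 0:
            return 0
        w = self.w
        q = (i - 1) // w  # word holding position i-1
        rem = i - q * w
        mask = (1 << rem) - 1
        return int(self.disp[a - 1, q]) + (self.words[a - 1][q] & mask).bit_count()


def compress_occ(bwt: np.ndarray | str, w: int) -> OccTable:
    return OccTable.build(bwt, w)


def occ(tab: OccTable, a: int | str, i: int) -> int:
    """Functional wrapper; ``a`` may be a base character or code."""
    if isinstance(a, str):
        a = _CODE[a]
    return tab.occ(a, i)


@dataclass
class CompressedSA:
    """Sampled SA/ISA: ``Scomp[k] = S[k*r]``, ``Rcomp[k] = R[k*r]``.

    ``marked`` maps a rank to its (multiple-of-r) text position; a rank is in
    ``marked`` exactly when its suffix position is stored, which is the stop
    condition of the psi-inverse reconstruction walk.
    """

    r: int
    scomp: np.ndarray
    rcomp: np.ndarray
    marked: dict = field(repr=False)

    @classmethod
    def build(cls, sa: np.ndarray, r: int) -> "CompressedSA":
        if r < 1:
            raise ValueError("compression ratio must be >= 1")
        n = sa.size
        isa = np.empty(n, dtype=np.int64)
        isa[sa] = np.arange(n)
        scomp = sa[::r].astype(np.int64)
        rcomp = isa[::r].astype(np.int64)
        marked = {int(rank): int(k * r) for k, rank in enumerate(rcomp)}
        return cls(r, scomp, rcomp, marked)


class FMSide:
    """The searchable structures for one orientation of the text."""

    __slots__ = ("n", "bwt", "C", "occtab", "csa", "sentinel_rank")

    def __init__(self, codes: np.ndarray, w: int, r: int):
        _validate_text(codes)
        sa = build_suffix_array(codes)
        self.n = codes.size
        self.bwt = bwt_from_sa(codes, sa)
        self.C = compute_C(self.bwt)
        self.occtab = OccTable.build(self.bwt, w)
        self.csa = CompressedSA.build(sa, r)
        self.sentinel_rank = int(np.flatnonzero(self.bwt == SENTINEL)[0])

    def occ(self, a: int, i: int) -> int:
        return self.occtab.occ(a, i)

    def psi_inverse(self, i: int) -> int:
        """Rank of the suffix one text position earlier: Psi^-1(i) = C(B[i]) + O(B[i], i+1).

        At the sentinel's BWT row the previous position wraps to the text end,
        whose suffix ("$") always has rank 0; reconstruction walks stop at a
        stored sample before ever reaching it.
        """
        if not 0 <= i < self.n:
            raise IndexError("rank out of range")
        a = int(self.bwt[i])
        if a == SENTINEL:
            return 0
        return int(self.C[a - 1]) + self.occtab.occ(a, i + 1)

    def sa(self, k: int) -> int:
        """S[k], reconstructed: walk Psi^-1 until a sampled rank, add steps."""
        if not 0 <= k < self.n:
            raise IndexError("rank out of range")
        marked = self.csa.marked
        j = 0
        t = k
        while t not in marked:
            t = self.psi_inverse(t)
            j += 1
        return marked[t] + j

    def isa(self, k: int) -> int:
        """R[k], reconstructed: R[k] = (Psi^-1)^(j')(R[k + j']), j' = (r - k mod r) mod r."""
        if not 0 <= k < self.n:
            raise IndexError("text position out of range")
        r = self.csa.r
        jp = (r - (k % r)) % r
        if k + jp < self.n:
            t = int(self.csa.rcomp[(k + jp) // r])
            steps = jp
        else:
            # k lies in the final incomplete block: start from the sentinel
            # suffix (position n-1, always rank 0) and walk back to k
            t = 0
            steps = self.n - 1 - k
        for _ in range(steps):
            t = self.psi_inverse(t)
        return t


@dataclass
class RecordSpan:
    name: str
    start: int  # offset in the concatenated text
    length: int


class FMIndex:
    """FM-index of a reference (concatenated records) and of its reverse.

    ``n`` includes the sentinel. Position ``p`` in the reversed text maps to
    position ``n - 2 - p`` in the forward text; a length-``m`` match starting
    at reversed position ``p`` starts at forward position ``n - 1 - p - m``.
    """

    def __init__(
        self,
        text: str,
        records: list[RecordSpan] | None = None,
        w: int = 64,
        r: int = 16,
    ):
        if not text or "$" in text:
            raise ValueError("reference must be a non-empty $-free string")
        self.fwd = FMSide(encode(text + "$"), w, r)
        self.rev = FMSide(encode(text[::-1] + "$"), w, r)
        self.n = len(text) + 1
        self.w = w
        self.r = r
        self.records = records or [RecordSpan("ref", 0, len(text))]

    def side(self, reverse: bool) -> FMSide:
        return self.rev if reverse else self.fwd

    def record_at(self, start: int, span: int) -> tuple[str, int] | None:
        """Record name and offset for a match, or None if it crosses a boundary."""
        for rec in self.records:
            if rec.start <= start and start + span <= rec.start + rec.length:
                return rec.name, start - rec.start
        return None


def sa_lookup(index: FMIndex, k: int, reverse: bool = False) -> int:
    return index.side(reverse).sa(k)


def isa_lookup(index: FMIndex, k: int, reverse: bool = False) -> int:
    return index.side(reverse).isa(k)


def psi_inverse(index: FMIndex, i: int, reverse: bool = False) -> int:
    return index.side(reverse).psi_inverse(i)


def _mask_reference(seq: str, seed: int) -> tuple[str, list[int]]:
    """Replace N bases with seeded random bases; return the masked positions."""
    positions = [i for i, c in enumerate(seq) if c == "N"]
    if not positions:
        return seq, []
    rng = np.random.default_rng(seed)
    chars = list(seq)
    for i in positions:
        chars[i] = ALPHABET[rng.integers(4)]
    return "".join(chars), positions


def build_index(
    reference,
    w: int = 64,
    r: int = 16,
    n_mask_seed: int = 0,
) -> FMIndex:
    """Build forward+reverse structures from a reference.

    ``reference`` may be a plain sequence string or a list of
    ``(name, sequence)`` pairs (multi-record references are concatenated and
    a boundary table retained so hits crossing records can be rejected).
    N bases are replaced by seeded random bases; the mask is recorded on the
    returned index as ``n_mask``.
    """
    if isinstance(reference, str):
        reference = [("ref", reference)]
    records: list[RecordSpan] = []
    parts: list[str] = []
    masked_all: list[int] = []
    offset = 0
    for name, seq in reference:
        seq = seq.upper()
        if not seq:
            raise ValueError(f"empty sequence in record {name!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"record {name!r} has symbols outside ACGTN: {sorted(bad)}")
        seq, masked = _mask_reference(seq, n_mask_seed + offset)
        masked_all.extend(offset + i for i in masked)
        records.append(RecordSpan(name, offset, len(seq)))
        parts.append(seq)
        offset += len(seq)
    if not parts:
        raise ValueError("reference has no records")
    idx = FMIndex("".join(parts), records, w=w, r=r)
    idx.n_mask = masked_all
    return idx


def _pack_side(side: FMSide, prefix: str, payload: dict) -> None:
    payload[f"{prefix}_bwt"] = side.bwt
    payload[f"{prefix}_scomp"] = side.csa.scomp
    payload[f"{prefix}_rcomp"] = side.csa.rcomp
    payload[f"{prefix}_disp"] = side.occtab.disp
    payload[f"{prefix}_words"] = np.array(
        [[w for w in row] for row in side.occtab.words], dtype=np.uint64
    )


def _unpack_side(prefix: str, data, w: int, r: int) -> FMSide:
    side = FMSide.__new__(FMSide)
    side.bwt = data[f"{prefix}_bwt"]
    side.n = side.bwt.size
    side.C = compute_C(side.bwt)
    words = data[f"{prefix}_words"]
    nwords = (side.n + w - 1) // w
    disp = data[f"{prefix}_disp"]
    side.occtab = OccTable(
        w, side.n, [[int(x) for x in words[a]] for a in range(4)], disp
    )
    scomp = data[f"{prefix}_scomp"].astype(np.int64)
    rcomp = data[f"{prefix}_rcomp"].astype(np.int64)
    marked = {int(rank): int(k * r) for k, rank in enumerate(rcomp)}
    side.csa = CompressedSA(r, scomp, rcomp, marked)
    side.sentinel_rank = int(np.flatnonzero(side.bwt == SENTINEL)[0])
    assert nwords == len(side.occtab.words[0])
    return side


def save_index(index: FMIndex, path) -> None:
    """Serialize to a single versioned .npz file; round trip is bit-exact."""
    meta = {
        "format_version": INDEX_FORMAT_VERSION,
        "n": index.n,
        "w": index.w,
        "r": index.r,
        "records": [[rec.name, rec.start, rec.length] for rec in index.records],
        "n_mask": list(getattr(index, "n_mask", [])),
    }
    payload = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    _pack_side(index.fwd, "fwd", payload)
    _pack_side(index.rev, "rev", payload)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_index(path) -> FMIndex:
    try:
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
    except Exception as exc:
        raise ValueError(f"corrupt or unreadable index file {path}: {exc}") from exc
    if meta.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"index format version {meta.get('format_version')} not supported"
        )
    idx = FMIndex.__new__(FMIndex)
    idx.n = meta["n"]
    idx.w = meta["w"]
    idx.r = meta["r"]
    idx.records = [RecordSpan(name, start, length) for name, start, length in meta["records"]]
    idx.n_mask = meta["n_mask"]
    idx.fwd = _unpack_side("fwd", data, idx.w, idx.r)
    idx.rev = _unpack_side("rev", data, idx.w, idx.r)
    return idx
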