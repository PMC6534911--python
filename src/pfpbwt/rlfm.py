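"""Counting-only run-length FM-index.

The BWT is stored as its maximal equal-symbol runs (head symbol, length,
start position). Rank queries are answered by binary search over the run
starts of the queried symbol plus per-symbol cumulative run lengths — a
structure contract-equivalent to a wavelet tree over the run heads with
marking bitvectors, chosen here for simplicity at the same asymptotics in
the number of runs ``r``.

Backward search (``count``) uses the LF mapping
``LF(i) = rank_{BWT[i]}(i) + C[BWT[i]]`` with the ``C`` array built from
the BWT's symbol histogram. A suffix-array sample at run boundaries can be
produced post hoc by "back-stepping": walking the LF permutation once
through the whole BWT, which recovers each row's text position; only the
rows that start or end a run are recorded. The walk materializes a dense
LF array, so — unlike counting — it needs memory linear in the text, which
is the known cost of building the sample after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import MIN_TEXT_BYTE, SENTINEL_DOLLAR
from .errors import InputError, InternalConsistencyError


@dataclass
class RLBWT:
    """Run-length encoded BWT with rank support."""

    run_heads: np.ndarray  # uint8, one symbol per maximal run
    run_lengths: np.ndarray  # int64, positive
    run_starts: np.ndarray = field(init=False)
    length: int = field(init=False)
    _per_symbol: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.run_heads = np.asarray(self.run_heads, dtype=np.uint8)
        self.run_lengths = np.asarray(self.run_lengths, dtype=np.int64)
        if len(self.run_heads) == 0:
            raise InputError("empty BWT")
        if (self.run_lengths <= 0).any():
            raise InputError("run lengths must be positive")
        if (self.run_heads[1:] == self.run_heads[:-1]).any():
            raise InputError("adjacent runs must have distinct head symbols")
        self.run_starts = np.concatenate(
            [[0], np.cumsum(self.run_lengths)[:-1]]
        ).astype(np.int64)
        self.length = int(self.run_lengths.sum())
        self._per_symbol = {}
        for c in np.unique(self.run_heads):
            mask = self.run_heads == c
            starts = self.run_starts[mask]
            lens = self.run_lengths[mask]
            self._per_symbol[int(c)] = (starts, lens, np.cumsum(lens))

    @property
    def r(self) -> int:
        """Number of maximal runs."""
        return len(self.run_heads)

    def decode(self) -> bytes:
        return bytes(np.repeat(self.run_heads, self.run_lengths))

    def symbol_at(self, i: int) -> int:
        if not 0 <= i < self.length:
            raise InputError(f"position {i} out of range [0, {self.length})")
        run = int(np.searchsorted(self.run_starts, i, side="right")) - 1
        return int(self.run_heads[run])

    def rank(self, c: int, i: int) -> int:
        """Occurrences of symbol ``c`` in ``BWT[0:i)``."""
        if not 0 <= i <= self.length:
            raise InputError(f"position {i} out of range [0, {self.length}]")
        entry = self._per_symbol.get(int(c))
        if entry is None:
            return 0
        starts, lens, cum = entry
        k = int(np.searchsorted(starts, i, side="right"))
        if k == 0:
            return 0
        before = int(cum[k - 2]) if k >= 2 else 0
        return before + min(int(lens[k - 1]), i - int(starts[k - 1]))

    def symbol_counts(self) -> np.ndarray:
        counts = np.zeros(256, dtype=np.int64)
        np.add.at(counts, self.run_heads.astype(np.int64), self.run_lengths)
        return counts

    def run_boundaries(self) -> np.ndarray:
        """All positions that start or end a maximal run (sorted, unique)."""
        ends = self.run_starts + self.run_lengths - 1
        return np.unique(np.concatenate([self.run_starts, ends]))


def run_length_encode(bwt: bytes) -> RLBWT:
    """Maximal-run decomposition of a BWT string."""
    if len(bwt) == 0:
        raise InputError("empty BWT")
    arr = np.frombuffer(bwt, dtype=np.uint8)
    change = np.flatnonzero(np.concatenate([[True], arr[1:] != arr[:-1]]))
    lengths = np.diff(np.concatenate([change, [len(arr)]]))
    return RLBWT(run_heads=arr[change], run_lengths=lengths)


@dataclass
class FArray:
    """``C[c]`` = number of BWT symbols strictly smaller than ``c``."""

    C: np.ndarray  # int64, length 256

    @classmethod
    def from_rlbwt(cls, index: RLBWT) -> "FArray":
        counts = index.symbol_counts()
        return cls(C=np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64))

    def __getitem__(self, c: int) -> int:
        return int(self.C[c])


@dataclass
class SASample:
    """Suffix-array samples recorded at run starts and run ends."""

    entries: list[tuple[int, int]]  # (BWT position, text position), ascending


def lf_map(index: RLBWT, F: FArray, i: int) -> int:
    """``LF(i) = rank_{BWT[i]}(i) + C[BWT[i]]``."""
    c = index.symbol_at(i)
    return index.rank(c, i) + F[c]


def _dense_lf(index: RLBWT) -> np.ndarray:
    """The full LF array (one entry per BWT position), vectorized."""
    arr = np.frombuffer(index.decode(), dtype=np.uint8).astype(np.int64)
    counts = np.zeros(256, dtype=np.int64)
    np.add.at(counts, arr, 1)
    C = np.concatenate([[0], np.cumsum(counts)[:-1]])
    lf = np.empty(len(arr), dtype=np.int64)
    for c in np.unique(arr):
        mask = arr == c
        lf[mask] = C[c] + np.arange(int(mask.sum()))
    return lf


def _lf_walk(index: RLBWT) -> np.ndarray:
    """Text position of each BWT row, by walking LF once around its cycle.

    Starts at row 0 — the row of the lone terminator suffix, whose text
    position is ``n`` — and steps backwards through the text. Raises if the
    walk does not return to the start in exactly ``n + 1`` steps.
    """
    L = index.length
    lf = _dense_lf(index)
    text_pos = np.full(L, -1, dtype=np.int64)
    cur = 0
    for pos in range(L - 1, -1, -1):
        if text_pos[cur] != -1:
            raise InternalConsistencyError("LF walk revisited a row: malformed BWT")
        text_pos[cur] = pos
        cur = int(lf[cur])
    # After L steps the walk must close its cycle at the start row.
    if cur != 0:
        raise InternalConsistencyError(
            "LF walk did not return to the start row: malformed BWT"
        )
    # pos assignment above walked suffix positions n, n-1, ..., 0; row 0 got n.
    return text_pos


def backstep_sample(index: RLBWT) -> SASample:
    """Build the run-boundary SA sample solely from the BWT."""
    text_pos = _lf_walk(index)
    boundaries = index.run_boundaries()
    return SASample(entries=[(int(b), int(text_pos[b])) for b in boundaries])


def invert_bwt(index: RLBWT) -> bytes:
    """Recover ``T $`` from its BWT."""
    if int(index.symbol_counts()[SENTINEL_DOLLAR]) != 1:
        raise InternalConsistencyError("BWT must contain exactly one terminator")
    text_pos = _lf_walk(index)
    arr = np.frombuffer(index.decode(), dtype=np.uint8)
    out = np.empty(index.length, dtype=np.uint8)
    # BWT[i] is the character at text_pos[i] - 1 (cyclically).
    out[(text_pos - 1) % index.length] = arr
    return bytes(out)


class RLFMIndex:
    """Run-length FM-index over a BWT, supporting ``count`` queries."""

    def __init__(self, rlbwt: RLBWT, sample: SASample | None = None):
        self.rlbwt = rlbwt
        self.F = FArray.from_rlbwt(rlbwt)
        self.sample = sample

    @classmethod
    def from_bwt(cls, bwt: bytes, sa_sample: bool = False) -> "RLFMIndex":
        rlbwt = run_length_encode(bwt)
        sample = backstep_sample(rlbwt) if sa_sample else None
        return cls(rlbwt, sample)

    @property
    def r(self) -> int:
        return self.rlbwt.r

    def count(self, pattern: bytes) -> int:
        """Number of occurrences of ``pattern`` in the indexed text."""
        if len(pattern) == 0:
            raise InputError("empty pattern")
        if any(b < MIN_TEXT_BYTE for b in pattern):
            raise InputError("pattern contains a reserved sentinel symbol")
        lo, hi = 0, self.rlbwt.length
        for c in reversed(pattern):
            lo = self.F[c] + self.rlbwt.rank(c, lo)
            hi = self.F[c] + self.rlbwt.rank(c, hi)
            if lo >= hi:
                return 0
        return hi - lo

    def save(self, path) -> None:
        arrays = {
            "run_heads": self.rlbwt.run_heads,
            "run_lengths": self.rlbwt.run_lengths,
        }
        if self.sample is not None:
            arrays["sample"] = np.asarray(self.sample.entries, dtype=np.int64)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "RLFMIndex":
        with np.load(path) as data:
            rlbwt = RLBWT(run_heads=data["run_heads"], run_lengths=data["run_lengths"])
            sample = None
            if "sample" in data:
                sample = SASample(entries=[tuple(row) for row in data["sample"]])
        return cls(rlbwt, sample)


def rank(index: RLBWT, c: int, i: int) -> int:
    """Module-level alias for :meth:`RLBWT.rank`."""
    return index.rank(c, i)


def count(index: RLFMIndex, pattern: bytes) -> int:
    """Module-level alias for :meth:`RLFMIndex.count`."""
    return index.count(pattern)
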