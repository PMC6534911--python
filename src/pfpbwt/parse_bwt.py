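"""BWT of the parse: per-phrase inverted lists and the permuted last array.

The parse ``P`` (a string over the integer alphabet of phrase ranks, with an
implicit terminator smaller than every rank) is suffix-sorted. Rather than
storing ``BWT(P)`` itself, we store the equivalent information in the form
used by the merge step:

* for each dictionary phrase ``d``, the **inverted list** of positions in
  ``BWT(P)`` at which ``d`` appears (ascending; its length equals ``d``'s
  frequency);
* the **permuted last array**: entry ``j`` is the ``W`` character of the
  phrase occurring two positions (cyclically) before the parse suffix of
  rank ``j`` — exactly the text symbol that precedes the phrase occurrence
  whose start that parse suffix encodes.

Suffix sorting is a numpy prefix-doubling (Manber-Myers) implementation;
any correct suffix sorter satisfies the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InternalConsistencyError
from .parsing import Dictionary, LastArray, ParseArray, ParseResult


def suffix_sort_ints(seq) -> np.ndarray:
    """Suffix array of a sequence of non-negative integers.

    Returns the permutation of start positions listing all suffixes in
    strictly increasing lexicographic order (a proper prefix sorts before
    any extension of it). O(n log n) rounds of radix-style ``lexsort``.
    """
    a = np.asarray(seq, dtype=np.int64)
    n = len(a)
    if n == 0:
        raise ValueError("cannot suffix-sort an empty sequence")
    if (a < 0).any():
        raise ValueError("sequence must be non-negative")
    # dense initial ranks
    _, rank = np.unique(a, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while True:
        if int(rank.max()) == n - 1:
            break
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            prev_diff = (rank[order][1:] != rank[order][:-1]) | (
                key2[order][1:] != key2[order][:-1]
            )
            changed[1:] = np.cumsum(prev_diff)
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = changed
        rank = new_rank
        k *= 2
    sa = np.empty(n, dtype=np.int64)
    sa[rank] = np.arange(n)
    return sa


@dataclass
class ParseBWTArtifacts:
    """Inverted lists of BWT(P) positions plus the permuted last array."""

    inverted_lists: list[list[int]]  # one ascending list per phrase rank
    permuted_last: bytes  # length z

    @property
    def z(self) -> int:
        return len(self.permuted_last)

    def validate(self, dictionary: Dictionary) -> None:
        seen = sorted(pos for lst in self.inverted_lists for pos in lst)
        if seen != list(range(self.z)):
            raise InternalConsistencyError(
                "inverted lists are not a permutation of 0..z-1"
            )
        for rank, lst in enumerate(self.inverted_lists):
            if len(lst) != int(dictionary.freqs[rank]):
                raise InternalConsistencyError(
                    f"inverted list of phrase {rank} has length {len(lst)}, "
                    f"expected frequency {int(dictionary.freqs[rank])}"
                )
            if any(b < a for a, b in zip(lst, lst[1:])):  # pragma: no cover
                raise InternalConsistencyError("inverted list not ascending")


def bwt_of_parse(
    parse: ParseArray, dictionary: Dictionary, last: LastArray
) -> ParseBWTArtifacts:
    """Suffix-sort the parse and bucket BWT(P) positions by phrase.

    With ranks shifted up by one and a 0 terminator appended, the ``z``
    suffixes starting at indices ``t = 1 .. z`` are taken in lexicographic
    order; the suffix of rank ``j`` contributes position ``j`` to the
    inverted list of phrase ``P[t-1]`` (the phrase preceding the suffix, a
    BWT(P) character), and ``permuted_last[j]`` is the ``W`` character of
    ``P[t-2]``, cyclically (``P[-1]`` is the final phrase — whose ``W``
    character is the last symbol of the text, which is what must precede
    the all-``$`` suffix).
    """
    z = parse.z
    if len(last.chars) != z:
        raise InternalConsistencyError("last array length != z")
    shifted = np.concatenate([parse.ranks + 1, [0]])
    sa = suffix_sort_ints(shifted)

    inverted: list[list[int]] = [[] for _ in range(len(dictionary))]
    permuted = bytearray(z)
    j = 0
    for t in sa:
        t = int(t)
        if t == 0:  # the whole-parse suffix encodes no phrase occurrence
            continue
        inverted[int(parse.ranks[t - 1])].append(j)
        permuted[j] = last.chars[(t - 2) % z]
        j += 1
    if j != z:
        raise InternalConsistencyError("parse suffix count != z")
    art = ParseBWTArtifacts(inverted_lists=inverted, permuted_last=bytes(permuted))
    art.validate(dictionary)
    return art


def parse_bwt_artifacts(result: ParseResult) -> ParseBWTArtifacts:
    """Convenience wrapper over :func:`bwt_of_parse` for a parse run."""
    return bwt_of_parse(result.parse, result.dictionary, result.last)
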