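"""Assemble the BWT of ``T $`` from the dictionary and parse artifacts.

The suffixes of the dictionary phrases of length greater than ``w`` (the set
``S``) are prefix-free, and every text suffix longer than ``w`` is prefixed
by exactly one of them, so sorting ``S`` partially sorts the suffixes of the
text. Scanning the sorted groups of equal suffixes and emitting, for each
group, the characters that precede its occurrences yields the BWT:

* a group whose only source is a *proper* suffix of a single phrase is
  preceded everywhere by one fixed character — emit it ``frequency`` times,
  no parse information needed;
* otherwise (several source phrases, and/or the suffix is a complete
  phrase) the occurrences are interleaved by merging the sources' inverted
  lists in ascending BWT(P) position, which by the order-agreement between
  parse suffixes and text suffixes is their order in the BWT. A proper
  source always contributes its fixed preceding character; a full-phrase
  source contributes the permuted-last character at the popped position.

The prepended ``#`` precedes exactly one text suffix (the whole of ``T $``),
so exactly one emission is the ``#`` symbol; it is rendered as the ``$``
terminator of the output BWT.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterator, Literal

from .alphabet import SENTINEL_DOLLAR, SENTINEL_HASH
from .errors import InternalConsistencyError
from .parse_bwt import ParseBWTArtifacts
from .parsing import Dictionary

PLACEHOLDER = ord("-")


@dataclass(frozen=True)
class SuffixSource:
    """One phrase contributing occurrences of a suffix-group's string."""

    rank: int  # 0-based dictionary rank of the source phrase
    kind: Literal["proper", "full-phrase"]
    preceding: int | None  # fixed preceding symbol; None for full-phrase


@dataclass(frozen=True)
class SuffixGroup:
    suffix: bytes
    sources: tuple[SuffixSource, ...]


def sort_dict_suffixes(dictionary: Dictionary, w: int) -> Iterator[SuffixGroup]:
    """Yield groups of equal phrase suffixes (length > w) in lexicographic order.

    Grouping is by suffix string equality over the sorted multiset of all
    phrase suffixes; dictionaries are small relative to the text, so the
    direct sort is the whole mechanism.
    """
    entries: list[tuple[bytes, int, str, int | None]] = []
    for rank, phrase in enumerate(dictionary.phrases):
        for start in range(len(phrase) - w):
            if start == 0:
                entries.append((phrase, rank, "full-phrase", None))
            else:
                entries.append((phrase[start:], rank, "proper", phrase[start - 1]))
    entries.sort(key=lambda e: (e[0], e[1]))

    i = 0
    while i < len(entries):
        j = i
        while j < len(entries) and entries[j][0] == entries[i][0]:
            j += 1
        yield SuffixGroup(
            suffix=entries[i][0],
            sources=tuple(
                SuffixSource(rank=r, kind=k, preceding=c)
                for _, r, k, c in entries[i:j]
            ),
        )
        i = j


def _group_emission(
    group: SuffixGroup, dictionary: Dictionary, art: ParseBWTArtifacts
) -> bytes:
    """Characters this group contributes to the BWT, in BWT order."""
    if len(group.sources) == 1 and group.sources[0].kind == "proper":
        src = group.sources[0]
        return bytes([src.preceding]) * int(dictionary.freqs[src.rank])
    def stream(src: SuffixSource):
        positions = art.inverted_lists[src.rank]
        if src.kind == "proper":
            return ((pos, src.preceding) for pos in positions)
        return ((pos, art.permuted_last[pos]) for pos in positions)

    return bytes(c for _, c in heapq.merge(*(stream(s) for s in group.sources)))


def construct_bwt(
    dictionary: Dictionary, parse_artifacts: ParseBWTArtifacts, w: int
) -> bytes:
    """The BWT of ``T $`` (terminator stored as the ``$`` sentinel byte)."""
    out = bytearray()
    for group in sort_dict_suffixes(dictionary, w):
        out += _group_emission(group, dictionary, parse_artifacts)
    n_plus_1 = dictionary.mapped_characters(w)
    if len(out) != n_plus_1:
        raise InternalConsistencyError(
            f"emitted {len(out)} BWT characters, expected {n_plus_1}"
        )
    if out.count(SENTINEL_HASH) != 1:
        raise InternalConsistencyError("expected exactly one terminator emission")
    return bytes(out).replace(bytes([SENTINEL_HASH]), bytes([SENTINEL_DOLLAR]))


def easy_bwt_subsequence(
    dictionary: Dictionary,
    parse_artifacts: ParseBWTArtifacts,
    w: int,
    placeholder: int = PLACEHOLDER,
) -> bytes:
    """The BWT with placeholders where a group maps more than one character.

    A suffix group to which a single distinct character is mapped is fully
    determined without interleaving its occurrences — those positions are
    emitted. A group receiving two or more distinct characters needs the
    parse-order merge; its positions are replaced by ``placeholder``.
    """
    out = bytearray()
    for group in sort_dict_suffixes(dictionary, w):
        chunk = _group_emission(group, dictionary, parse_artifacts)
        if len(set(chunk)) > 1:
            chunk = bytes([placeholder]) * len(chunk)
        out += chunk
    return bytes(out).replace(bytes([SENTINEL_HASH]), bytes([SENTINEL_DOLLAR]))


def group_partial_sums(dictionary: Dictionary, w: int) -> list[int]:
    """Cumulative emission counts before each suffix group, in group order."""
    sums = []
    total = 0
    for group in sort_dict_suffixes(dictionary, w):
        sums.append(total)
        if len(group.sources) == 1 and group.sources[0].kind == "proper":
            total += int(dictionary.freqs[group.sources[0].rank])
        else:
            total += sum(int(dictionary.freqs[s.rank]) for s in group.sources)
    return sums
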