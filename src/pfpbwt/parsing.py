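"""Prefix-free parsing: dictionary, parse and last-character array.

A window of length ``w`` slides over the text. Whenever the window is a
*trigger* — a member of an explicit set ``E`` of length-``w`` strings, or a
window whose Karp-Rabin hash is 0 modulo ``p`` — the current phrase ends at
the end of the window and the next phrase starts at the window's *start*, so
consecutive phrases overlap by exactly ``w`` symbols. The text is wrapped as
``# T $^w`` before parsing: the first phrase starts with the prepended
``#``, the last ends with ``w`` copies of ``$``. Every phrase therefore
begins and ends with an element of ``E' = E ∪ {#, $^w}``, contains no other
occurrence of one, and has length greater than ``w``.

The products of one parsing run are:

* the **dictionary**: the distinct phrases in lexicographic order, with the
  number of times each occurs;
* the **parse**: the sequence of 0-based dictionary ranks of the phrase
  occurrences, in text order;
* the **last array** ``W``: for each phrase occurrence, its symbol at
  position ``w+1`` counted from the end — the symbol that immediately
  precedes the start of the *next* phrase, needed later when a full phrase
  shows up as a dictionary suffix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .alphabet import (
    DEFAULT_CONVENTIONS,
    SymbolConventions,
    to_display,
    validate_text,
)
from .errors import FingerprintCollisionError, InputError, InternalConsistencyError
from .hashing import (
    DEFAULT_BASE,
    DEFAULT_MODULUS,
    RollingHash,
    fingerprint,
    is_probable_prime,
)


class TriggerMode(str, Enum):
    EXPLICIT = "explicit-set"
    KARP_RABIN = "karp-rabin"


@dataclass(frozen=True)
class TriggerPolicy:
    """How phrase boundaries are recognized.

    Either an explicit set of length-``w`` trigger strings, or the
    content-defined rule "window hash ≡ 0 (mod p)".
    """

    w: int
    mode: TriggerMode
    explicit_set: frozenset[bytes] | None = None
    p: int | None = None
    hash_base: int = DEFAULT_BASE
    hash_modulus: int = DEFAULT_MODULUS

    def __post_init__(self):
        if self.w < 1:
            raise InputError("window length w must be >= 1")
        if self.mode is TriggerMode.EXPLICIT:
            if self.explicit_set is None:
                raise InputError("explicit-set policy requires a trigger set")
            for t in self.explicit_set:
                if len(t) != self.w:
                    raise InputError(
                        f"trigger string {t!r} has length {len(t)}, expected w={self.w}"
                    )
        else:
            # p = 1 is degenerate but well-defined: every window triggers.
            if self.p is None or self.p < 1:
                raise InputError("karp-rabin policy requires a modulus p >= 1")
            if self.hash_modulus <= self.hash_base:
                raise InputError("hash modulus must exceed the hash base")
            if not is_probable_prime(self.hash_modulus):
                raise InputError("hash modulus must be prime")

    @classmethod
    def explicit(cls, triggers, w: int | None = None) -> "TriggerPolicy":
        triggers = frozenset(
            t.encode() if isinstance(t, str) else bytes(t) for t in triggers
        )
        if w is None:
            if not triggers:
                raise InputError("cannot infer w from an empty trigger set")
            w = len(next(iter(triggers)))
        return cls(w=w, mode=TriggerMode.EXPLICIT, explicit_set=triggers)

    @classmethod
    def karp_rabin(cls, w: int, p: int, **kwargs) -> "TriggerPolicy":
        return cls(w=w, mode=TriggerMode.KARP_RABIN, p=p, **kwargs)


@dataclass(frozen=True)
class Phrase:
    """A dictionary phrase (bytes over the alphabet plus sentinels)."""

    symbols: bytes

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def display(self) -> str:
        return to_display(self.symbols)


@dataclass
class Dictionary:
    """Distinct phrases in strictly increasing lexicographic order."""

    phrases: list[bytes]
    freqs: np.ndarray  # positive int per phrase, aligned with `phrases`

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.phrases)

    @property
    def displays(self) -> list[str]:
        return [to_display(p) for p in self.phrases]

    def rank_of(self, phrase: bytes) -> int:
        """0-based lexicographic rank of ``phrase``; raises if absent."""
        import bisect

        i = bisect.bisect_left(self.phrases, phrase)
        if i == len(self.phrases) or self.phrases[i] != phrase:
            raise KeyError(f"phrase {to_display(phrase)!r} not in dictionary")
        return i

    def total_length(self) -> int:
        return sum(len(p) for p in self.phrases)

    def validate(self, w: int) -> None:
        """Check sortedness, distinctness and the character-count identity.

        ``sum freq * (len - w)`` must equal ``n + 1``: every character of
        ``T $`` is emitted exactly once when the BWT is later assembled.
        """
        for a, b in zip(self.phrases, self.phrases[1:]):
            if not a < b:
                raise InternalConsistencyError("dictionary phrases not strictly sorted")
        if len(self.phrases) != len(self.freqs):
            raise InternalConsistencyError("freqs not aligned with phrases")
        if any(len(p) <= w for p in self.phrases):
            raise InternalConsistencyError("phrase of length <= w")

    def mapped_characters(self, w: int) -> int:
        return int(sum(f * (len(p) - w) for p, f in zip(self.phrases, self.freqs)))


@dataclass
class ParseArray:
    """The parse ``P``: 0-based phrase ranks covering ``# T $^w``."""

    ranks: np.ndarray

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=np.int64)

    @property
    def z(self) -> int:
        return len(self.ranks)


@dataclass
class LastArray:
    """``W``: per occurrence, the phrase symbol at position w+1 from the end."""

    chars: bytes

    def __len__(self) -> int:
        return len(self.chars)


@dataclass(frozen=True)
class ParseResult:
    dictionary: Dictionary
    parse: ParseArray
    last: LastArray
    w: int
    n: int  # input text length

    def __iter__(self):
        return iter((self.dictionary, self.parse, self.last))


def is_trigger(window: bytes, policy: TriggerPolicy) -> bool:
    """Is this length-``w`` window a phrase boundary under ``policy``?"""
    if len(window) != policy.w:
        raise InputError(f"window has length {len(window)}, expected w={policy.w}")
    if policy.mode is TriggerMode.EXPLICIT:
        return window in policy.explicit_set
    from .hashing import hash_bytes

    return hash_bytes(window, policy.hash_base, policy.hash_modulus) % policy.p == 0


def _trigger_positions(text: bytes, policy: TriggerPolicy) -> list[int]:
    """Start positions (text coordinates) of all trigger windows."""
    n, w = len(text), policy.w
    if n < w:
        return []
    if policy.mode is TriggerMode.EXPLICIT:
        e = policy.explicit_set
        return [i for i in range(n - w + 1) if text[i:i + w] in e]
    out = []
    rh = RollingHash(text[:w], policy.hash_base, policy.hash_modulus)
    p = policy.p
    if rh.value % p == 0:
        out.append(0)
    for i in range(1, n - w + 1):
        if rh.roll(text[i - 1], text[i + w - 1]) % p == 0:
            out.append(i)
    return out


def last_w1_char(phrase: bytes, w: int) -> int:
    """The symbol of ``phrase`` at position ``w+1`` counted from the end."""
    if len(phrase) < w + 1:
        raise InputError(
            f"phrase of length {len(phrase)} has no position w+1={w + 1} from the end"
        )
    return phrase[len(phrase) - (w + 1)]


def parse_text(
    text: bytes,
    policy: TriggerPolicy,
    conventions: SymbolConventions = DEFAULT_CONVENTIONS,
) -> ParseResult:
    """Prefix-free parse of ``text`` under ``policy``.

    Phrase boundaries: every trigger-window occurrence ends the current
    phrase at the window's end and starts the next at the window's start.
    If the final ``w`` symbols of the text form a trigger, they begin the
    last phrase, to which ``$^w`` is then appended; otherwise ``$^w`` simply
    extends the phrase in progress. A text shorter than ``w`` (no complete
    window) yields the single phrase ``# T $^w``.

    Phrase deduplication is fingerprint-keyed with mandatory full-string
    verification; a verified collision aborts the parse.
    """
    if len(text) == 0:
        raise InputError("cannot parse an empty text")
    validate_text(text, conventions)

    n, w = len(text), policy.w
    wrapped = bytes([conventions.sentinel_hash]) + text + bytes([conventions.sentinel_dollar]) * w
    boundaries = _trigger_positions(text, policy)

    starts = [0] + [b + 1 for b in boundaries]  # wrapped coordinates
    ends = [b + 1 + w for b in boundaries] + [len(wrapped)]

    table: dict[int, list] = {}  # fingerprint -> [phrase bytes, freq]
    occ_fps: list[int] = []
    last_chars = bytearray()
    for s, e in zip(starts, ends):
        phrase = wrapped[s:e]
        fp = fingerprint(phrase, policy.hash_base, policy.hash_modulus)
        entry = table.get(fp)
        if entry is None:
            table[fp] = [phrase, 1]
        else:
            if entry[0] != phrase:
                raise FingerprintCollisionError(
                    f"fingerprint collision between phrases "
                    f"{to_display(entry[0])!r} and {to_display(phrase)!r}"
                )
            entry[1] += 1
        occ_fps.append(fp)
        last_chars.append(phrase[len(phrase) - (w + 1)])

    ordered = sorted(table.values(), key=lambda ent: ent[0])
    rank_by_fp = {
        fingerprint(ph, policy.hash_base, policy.hash_modulus): r
        for r, (ph, _) in enumerate(ordered)
    }
    dictionary = Dictionary(
        phrases=[ph for ph, _ in ordered],
        freqs=np.array([f for _, f in ordered], dtype=np.int64),
    )
    parse = ParseArray(np.array([rank_by_fp[fp] for fp in occ_fps], dtype=np.int64))
    last = LastArray(bytes(last_chars))

    dictionary.validate(w)
    if dictionary.mapped_characters(w) != n + 1:
        raise InternalConsistencyError("mapped character count != n + 1")
    return ParseResult(dictionary, parse, last, w=w, n=n)


def expand_parse(result: ParseResult) -> bytes:
    """Reassemble ``# T $^w`` from dictionary + parse (phrases overlap by w)."""
    w = result.w
    pieces = []
    for j, r in enumerate(result.parse.ranks):
        phrase = result.dictionary.phrases[int(r)]
        pieces.append(phrase if j == 0 else phrase[w:])
    return b"".join(pieces)


def suffix_set(dictionary: Dictionary, w: int) -> set[bytes]:
    """The set S: suffixes of dictionary phrases of length greater than w."""
    out: set[bytes] = set()
    for phrase in dictionary.phrases:
        for start in range(len(phrase) - w):
            out.add(phrase[start:])
    return out
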