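"""Symbol conventions: the byte alphabet and the two reserved sentinels.

The parser works on ``bytes``. Two byte values are reserved and must not
occur in any input text:

* ``SENTINEL_HASH`` (0x00) — the symbol prepended to the text, written ``#``;
* ``SENTINEL_DOLLAR`` (0x01) — the symbol appended ``w`` times to the text
  and used as the BWT terminator, written ``$``.

Both sort strictly below every admissible text symbol under plain byte
comparison, and ``# < $``, so native ``bytes`` ordering *is* the canonical
lexicographic order used throughout — no custom comparator is needed. The
relative order of the two sentinels themselves never decides a comparison
the algorithm performs (they are never aligned against each other in any
sorted set); the test suite asserts this by swapping the assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SentinelInInputError

SENTINEL_HASH = 0x00  # '#', prepended once
SENTINEL_DOLLAR = 0x01  # '$', appended w times; BWT terminator

#: Smallest byte value admissible in an input text.
MIN_TEXT_BYTE = 0x02


@dataclass(frozen=True)
class SymbolConventions:
    """The total order on symbols: ``# < $ < every byte of the alphabet``."""

    sentinel_hash: int = SENTINEL_HASH
    sentinel_dollar: int = SENTINEL_DOLLAR
    alphabet: frozenset[int] | None = None

    def __post_init__(self):
        if self.alphabet is None:
            object.__setattr__(
                self, "alphabet", frozenset(range(MIN_TEXT_BYTE, 256))
            )
        if not (self.sentinel_hash < self.sentinel_dollar < min(self.alphabet)):
            raise ValueError("sentinels must sort strictly below the alphabet")


DEFAULT_CONVENTIONS = SymbolConventions()


def validate_text(text: bytes, conventions: SymbolConventions = DEFAULT_CONVENTIONS) -> None:
    """Reject texts containing a reserved sentinel byte, naming the position."""
    for sentinel in (conventions.sentinel_hash, conventions.sentinel_dollar):
        pos = text.find(sentinel)
        if pos != -1:
            raise SentinelInInputError(pos, sentinel)


def to_display(data: bytes) -> str:
    """Render internal bytes as text, with sentinels shown as ``#`` and ``$``."""
    return "".join(
        "#" if b == SENTINEL_HASH else "$" if b == SENTINEL_DOLLAR else chr(b)
        for b in data
    )


def from_display(s: str) -> bytes:
    """Inverse of :func:`to_display` for ASCII strings."""
    return bytes(
        SENTINEL_HASH if c == "#" else SENTINEL_DOLLAR if c == "$" else ord(c)
        for c in s
    )
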