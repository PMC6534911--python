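"""Karp-Rabin rolling hash and phrase fingerprints.

Polynomial hash over a 61-bit Mersenne prime modulus,
``H(s) = sum_i s[i] * B^(L-1-i) mod M``. The multiplier ``B`` is a large
prime rather than the alphabet radix 256: with ``B = 256`` the residues of
``H`` modulo small trigger moduli stay correlated with individual window
bytes on narrow alphabets (for DNA windows, ``H mod 4`` is never 0, so a
trigger modulus like 100 would never fire). A large prime multiplier mixes
every byte into every residue class. The same polynomial serves two
purposes:

* the *window* hash that drives content-defined phrase boundaries (a window
  triggers when ``H(window) mod p == 0``), updated in O(1) as the window
  slides;
* the *phrase* fingerprint used to deduplicate phrases, always backed by a
  full string comparison so a fingerprint collision is detected (and raised)
  rather than silently merging two distinct phrases.
"""

from __future__ import annotations

DEFAULT_BASE = 27_162_335_252_586_509  # prime multiplier, < 2^61 - 1
DEFAULT_MODULUS = (1 << 61) - 1  # Mersenne prime 2^61 - 1


class RollingHash:
    """Incrementally maintained polynomial hash of a fixed-length window."""

    __slots__ = ("base", "modulus", "w", "value", "_msb_weight")

    def __init__(self, window: bytes, base: int = DEFAULT_BASE,
                 modulus: int = DEFAULT_MODULUS):
        self.base = base
        self.modulus = modulus
        self.w = len(window)
        self._msb_weight = pow(base, self.w - 1, modulus)
        self.value = hash_bytes(window, base, modulus)

    def roll(self, outgoing: int, incoming: int) -> int:
        """Shift the window by one symbol; returns the new hash value."""
        v = (self.value - outgoing * self._msb_weight) % self.modulus
        self.value = (v * self.base + incoming) % self.modulus
        return self.value


def hash_bytes(data: bytes, base: int = DEFAULT_BASE,
               modulus: int = DEFAULT_MODULUS) -> int:
    """From-scratch polynomial hash of ``data``."""
    h = 0
    for b in data:
        h = (h * base + b) % modulus
    return h


def fingerprint(data: bytes, base: int = DEFAULT_BASE,
                modulus: int = DEFAULT_MODULUS) -> int:
    """Phrase fingerprint: the same polynomial, keyed additionally by length.

    Mixing in the length keeps leading-zero-byte prefixes (the sentinels)
    from aliasing, since the plain polynomial ignores leading zeros.
    """
    return (hash_bytes(data, base, modulus) * base + len(data)) % modulus


def is_probable_prime(n: int) -> bool:
    """Deterministic Miller-Rabin for n < 3.3e24 (covers all 64-bit inputs)."""
    if n < 2:
        return False
    small = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37)
    for p in small:
        if n % p == 0:
            return n == p
    d, s = n - 1, 0
    while d % 2 == 0:
        d //= 2
        s += 1
    for a in small:
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True
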