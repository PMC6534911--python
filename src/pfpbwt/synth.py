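"""Synthetic repetitive collections for testing and benchmarking.

Emulates, at desk scale, the structure that makes genome collections
compress well under prefix-free parsing: one random base sequence plus many
near-identical copies differing by independent point substitutions (and,
optionally, short indels). Concatenating the copies yields a highly
repetitive text whose dictionary-plus-parse footprint shrinks relative to
the text as copies are added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

DNA = b"ACGT"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic collection.

    Defaults model a set of haplotype-like variants: DNA alphabet,
    substitution-only divergence (indels off).
    """

    seed: int = 0
    base_length: int = 1000
    copies: int = 10
    mutation_rate: float = 0.01  # per-symbol substitution probability
    indel_rate: float = 0.0  # per-symbol insertion/deletion probability
    alphabet: bytes = DNA

    def __post_init__(self):
        if self.base_length < 1:
            raise InputError("base_length must be >= 1")
        if self.copies < 1:
            raise InputError("copies must be >= 1")
        for rate in (self.mutation_rate, self.indel_rate):
            if not 0.0 <= rate < 1.0:
                raise InputError("rates must lie in [0, 1)")
        if len(set(self.alphabet)) < 2:
            raise InputError("alphabet needs at least two distinct symbols")


def synth_collection(config: SynthConfig) -> bytes:
    """Deterministic (per seed) concatenation of base + mutated copies."""
    rng = np.random.default_rng(config.seed)
    sigma = np.frombuffer(bytes(sorted(set(config.alphabet))), dtype=np.uint8)
    k = len(sigma)
    idx = rng.integers(0, k, size=config.base_length)
    pieces = [sigma[idx].tobytes()]
    for _ in range(config.copies - 1):
        variant = idx.copy()
        sub_mask = rng.random(len(variant)) < config.mutation_rate
        n_sub = int(sub_mask.sum())
        if n_sub:
            # substitute with a uniformly random *different* symbol
            shift = rng.integers(1, k, size=n_sub)
            variant[sub_mask] = (variant[sub_mask] + shift) % k
        if config.indel_rate > 0.0:
            variant = _apply_indels(variant, rng, config.indel_rate, k)
        pieces.append(sigma[variant].tobytes())
    return b"".join(pieces)


def _apply_indels(variant: np.ndarray, rng, rate: float, k: int) -> np.ndarray:
    """Per-symbol deletion (rate/2) or single-symbol insertion (rate/2)."""
    out = []
    dels = rng.random(len(variant)) < rate / 2
    ins = rng.random(len(variant)) < rate / 2
    ins_sym = rng.integers(0, k, size=len(variant))
    for i, sym in enumerate(variant):
        if ins[i]:
            out.append(int(ins_sym[i]))
        if not dels[i]:
            out.append(int(sym))
    if not out:  # degenerate: everything deleted
        out = [int(variant[0])]
    return np.asarray(out, dtype=variant.dtype)
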