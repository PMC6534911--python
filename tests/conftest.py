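"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pfpbwt import SENTINEL_DOLLAR, TriggerPolicy, parse_text
from pfpbwt import demo

ALPHABETS = {
    2: b"AC",
    4: b"ACGT",
    20: bytes(range(65, 85)),  # A..T
}


def naive_suffix_sort(seq) -> list[int]:
    """Sort-all-suffixes oracle, independent of the prefix-doubling sorter."""
    seq = list(seq)
    return sorted(range(len(seq)), key=lambda i: seq[i:])


def rotation_bwt(text: bytes) -> bytes:
    """BWT by sorting all rotations of the terminated text (independent of
    any suffix-array code): last column of the sorted rotation matrix."""
    t = text + bytes([SENTINEL_DOLLAR])
    rotations = sorted(t[i:] + t[:i] for i in range(len(t)))
    return bytes(r[-1] for r in rotations)


def random_text(rng: np.random.Generator, sigma: bytes, n: int) -> bytes:
    return bytes(rng.choice(np.frombuffer(sigma, dtype=np.uint8), size=n))


def random_explicit_policy(rng: np.random.Generator, sigma: bytes, w: int) -> TriggerPolicy:
    universe = [bytes(t) for t in itertools.product(sigma, repeat=w)]
    k = min(len(universe), int(rng.integers(1, 8)))
    chosen = [universe[i] for i in rng.choice(len(universe), size=k, replace=False)]
    return TriggerPolicy.explicit(chosen, w=w)


def random_instances(seed: int, count: int, max_len: int = 2000):
    """Yield (text, policy) pairs over both trigger modes and several alphabets."""
    rng = np.random.default_rng(seed)
    ps = [3, 5, 11, 31]
    sigmas = list(ALPHABETS.values())
    for i in range(count):
        sigma = sigmas[i % len(sigmas)]
        w = 2 + (i // len(sigmas)) % 3
        n = int(rng.integers(1, max_len + 1))
        text = random_text(rng, sigma, n)
        if i % 5 == 4:
            policy = random_explicit_policy(rng, sigma, w)
        else:
            policy = TriggerPolicy.karp_rabin(w=w, p=ps[i % len(ps)])
        yield text, policy


@pytest.fixture(scope="session")
def worked():
    """The hand-checkable GATTACA instance, parsed once per session."""
    policy = TriggerPolicy.explicit(demo.TRIGGERS, w=demo.W)
    return parse_text(demo.TEXT, policy)
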