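"""Brute-force oracles: direct BWT, suffix array and substring counting.

These compute the same quantities as the parsing pipeline by the obvious
direct route (suffix-sort the whole text) and exist so that every pipeline
result can be checked exactly on synthetic inputs. They share only the
integer suffix sorter with the pipeline; the sorter itself is verified
against a naive sort-all-suffixes comparison in the test suite, and the
direct BWT is additionally cross-checked there against an independent
rotation-sort implementation.
"""

from __future__ import annotations

import numpy as np

from .alphabet import SENTINEL_DOLLAR, validate_text
from .parse_bwt import suffix_sort_ints


def brute_suffix_array(terminated: bytes) -> np.ndarray:
    """Suffix array of an already-terminated byte string."""
    return suffix_sort_ints(np.frombuffer(terminated, dtype=np.uint8))


def brute_bwt(text: bytes) -> bytes:
    """BWT of ``text + $`` by direct suffix sorting.

    The character preceding each sorted suffix is emitted; the whole-string
    suffix is preceded (cyclically) by the terminator.
    """
    validate_text(text)
    t = text + bytes([SENTINEL_DOLLAR])
    sa = brute_suffix_array(t)
    arr = np.frombuffer(t, dtype=np.uint8)
    return bytes(arr[(sa - 1) % len(t)])


def brute_count(text: bytes, pattern: bytes) -> int:
    """Naive overlapping-occurrence count of ``pattern`` in ``text``."""
    if len(pattern) == 0 or len(pattern) > len(text):
        return 0
    count = 0
    start = text.find(pattern)
    while start != -1:
        count += 1
        start = text.find(pattern, start + 1)
    return count
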