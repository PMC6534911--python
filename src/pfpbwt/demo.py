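"""The GATTACA demo: a tiny instance small enough to verify by hand.

``T = GATTACAT!GATACAT!GATTAGATA`` parsed with ``w = 2`` and the explicit
trigger set ``{AC, AG, T!}`` produces a five-phrase dictionary, the parse
``[0, 1, 3, 1, 4, 2]``, and a 27-symbol BWT. Every value here is fixed by
hand-checkable enumeration, which makes the instance a golden fixture for
the ``pfp selftest`` command and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import from_display
from .merge import easy_bwt_subsequence
from .parse_bwt import parse_bwt_artifacts
from .parsing import TriggerPolicy, parse_text
from .pipeline import bwt_from_parse
from .serialization import bwt_to_text

TEXT = b"GATTACAT!GATACAT!GATTAGATA"
W = 2
TRIGGERS = ("AC", "AG", "T!")

DICTIONARY = ["#GATTAC", "ACAT!", "AGATA$$", "T!GATAC", "T!GATTAG"]
PARSE = [0, 1, 3, 1, 4, 2]
FREQS = [1, 2, 1, 1, 1]
BWT = "ATTTTTTCCGGGGAAA!$!AAATATAA"
EASY_BWT = "ATTTTTTCCGGGGAAA!$!AAA--TAA"


@dataclass
class SelfTestReport:
    passed: bool
    failures: list[str]


def run_selftest() -> SelfTestReport:
    """Run the demo end-to-end and compare every artifact to its known value."""
    failures: list[str] = []
    policy = TriggerPolicy.explicit(TRIGGERS, w=W)
    result = parse_text(TEXT, policy)

    if result.dictionary.displays != DICTIONARY:
        failures.append(f"dictionary {result.dictionary.displays} != {DICTIONARY}")
    if list(result.parse.ranks) != PARSE:
        failures.append(f"parse {list(result.parse.ranks)} != {PARSE}")
    if list(result.dictionary.freqs) != FREQS:
        failures.append(f"freqs {list(result.dictionary.freqs)} != {FREQS}")

    bwt = bwt_from_parse(result)
    if bwt_to_text(bwt) != BWT:
        failures.append(f"BWT {bwt_to_text(bwt)!r} != {BWT!r}")

    art = parse_bwt_artifacts(result)
    easy = easy_bwt_subsequence(result.dictionary, art, W)
    if bwt_to_text(easy) != EASY_BWT:
        failures.append(f"easy subsequence {bwt_to_text(easy)!r} != {EASY_BWT!r}")

    expected_bwt = from_display(BWT)
    from .oracle import brute_bwt

    if brute_bwt(TEXT) != expected_bwt:
        failures.append("direct suffix-sort BWT disagrees with the known value")

    return SelfTestReport(passed=not failures, failures=failures)
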