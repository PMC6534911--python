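"""End-to-end conveniences: text -> BWT -> index in one call."""

from __future__ import annotations

from .merge import construct_bwt
from .parse_bwt import parse_bwt_artifacts
from .parsing import ParseResult, TriggerPolicy, parse_text
from .rlfm import RLFMIndex


def build_bwt(text: bytes, policy: TriggerPolicy) -> bytes:
    """Parse ``text`` and assemble the BWT of ``text + $``."""
    result = parse_text(text, policy)
    return bwt_from_parse(result)


def bwt_from_parse(result: ParseResult) -> bytes:
    art = parse_bwt_artifacts(result)
    return construct_bwt(result.dictionary, art, result.w)


def build_index(
    text: bytes, policy: TriggerPolicy, sa_sample: bool = False
) -> RLFMIndex:
    """Parse, build the BWT, and wrap it in a counting run-length FM-index."""
    return RLFMIndex.from_bwt(build_bwt(text, policy), sa_sample=sa_sample)
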