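"""On-disk artifacts: the parse bundle, input readers and BWT writers.

A parsing run is persisted as four files sharing a path prefix plus a JSON
metadata sidecar:

* ``.dict`` — phrases in lexicographic order, each followed by the
  end-of-phrase terminator byte 0x01. On disk the ``#`` sentinel is stored
  as 0x01 and ``$`` as 0x00; since ``#`` can only be the very first byte of
  the file (the ``#`` phrase sorts first) and ``$`` only occurs inside the
  final-in-text phrase's tail, a 0x01 anywhere past offset 0 unambiguously
  terminates a phrase.
* ``.parse`` — the ``z`` phrase ranks as little-endian 4-byte unsigned ints;
* ``.occ``  — per-phrase frequencies in rank order, same encoding;
* ``.last`` — the ``z`` last-array characters as raw bytes (``#`` as 0x01);
* ``.meta.json`` — ``w``, a policy description, and the text length ``n``.

Reading a written bundle reproduces the in-memory objects exactly, and
writing the same objects twice yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import SENTINEL_DOLLAR, SENTINEL_HASH
from .errors import BundleFormatError, InputError
from .parsing import Dictionary, LastArray, ParseArray, ParseResult

_U32_MAX = 2**32 - 1
_EOW = 0x01  # end-of-phrase terminator byte in the .dict file
_DISK_HASH = 0x01  # on-disk byte for the '#' sentinel
_DISK_DOLLAR = 0x00  # on-disk byte for the '$' sentinel

EXTENSIONS = (".dict", ".parse", ".occ", ".last")


@dataclass(frozen=True)
class ArtifactBundle:
    """File locations and metadata of one persisted parsing run."""

    dict_path: Path
    parse_path: Path
    occ_path: Path
    last_path: Path
    meta_path: Path
    w: int | None = None
    policy: str | None = None
    n: int | None = None

    @classmethod
    def at(cls, prefix, **meta) -> "ArtifactBundle":
        prefix = Path(prefix)
        return cls(
            dict_path=prefix.with_suffix(prefix.suffix + ".dict"),
            parse_path=prefix.with_suffix(prefix.suffix + ".parse"),
            occ_path=prefix.with_suffix(prefix.suffix + ".occ"),
            last_path=prefix.with_suffix(prefix.suffix + ".last"),
            meta_path=prefix.with_suffix(prefix.suffix + ".meta.json"),
            **meta,
        )


def _phrase_to_disk(phrase: bytes) -> bytes:
    out = bytearray()
    for b in phrase:
        if b == SENTINEL_HASH:
            out.append(_DISK_HASH)
        elif b == SENTINEL_DOLLAR:
            out.append(_DISK_DOLLAR)
        else:
            out.append(b)
    return bytes(out)


def _last_to_disk(chars: bytes) -> bytes:
    return chars.replace(bytes([SENTINEL_HASH]), bytes([_DISK_HASH]))


def _last_from_disk(chars: bytes) -> bytes:
    return chars.replace(bytes([_DISK_HASH]), bytes([SENTINEL_HASH]))


def write_bundle(
    dictionary: Dictionary,
    parse: ParseArray,
    last: LastArray,
    dest,
    w: int | None = None,
    policy: str | None = None,
) -> ArtifactBundle:
    """Persist one parsing run under path prefix ``dest``."""
    if len(dictionary) == 0:
        raise InputError("refusing to write an empty dictionary")
    if len(dictionary) > _U32_MAX or parse.z > _U32_MAX:
        raise InputError("bundle exceeds the 4-byte integer format limit")
    hist = np.bincount(parse.ranks, minlength=len(dictionary))
    if not np.array_equal(hist, dictionary.freqs):
        raise InputError("frequency histogram of parse does not match dictionary")

    n = dictionary.mapped_characters(w) - 1 if w is not None else None
    bundle = ArtifactBundle.at(dest, w=w, policy=policy, n=n)

    with open(bundle.dict_path, "wb") as f:
        for phrase in dictionary.phrases:
            f.write(_phrase_to_disk(phrase))
            f.write(bytes([_EOW]))
    parse.ranks.astype("<u4").tofile(bundle.parse_path)
    dictionary.freqs.astype("<u4").tofile(bundle.occ_path)
    with open(bundle.last_path, "wb") as f:
        f.write(_last_to_disk(last.chars))
    bundle.meta_path.write_text(
        json.dumps({"w": w, "policy": policy, "n": n}, sort_keys=True) + "\n"
    )
    return bundle


def _split_dict_file(raw: bytes) -> list[bytes]:
    if not raw:
        raise BundleFormatError("empty dictionary file")
    if raw[-1] != _EOW:
        raise BundleFormatError("dictionary file does not end with a terminator")
    phrases = []
    current = bytearray()
    for offset, b in enumerate(raw):
        if b == _EOW and offset > 0:
            if not current:
                raise BundleFormatError("empty phrase in dictionary file")
            phrases.append(bytes(current))
            current = bytearray()
        elif b == _DISK_HASH:  # offset 0 only: the '#' phrase head
            current.append(SENTINEL_HASH)
        elif b == _DISK_DOLLAR:
            current.append(SENTINEL_DOLLAR)
        else:
            current.append(b)
    return phrases


def read_bundle(src) -> tuple[Dictionary, ParseArray, LastArray]:
    """Inverse of :func:`write_bundle`; validates mutual consistency."""
    bundle = ArtifactBundle.at(src)
    for path in (bundle.dict_path, bundle.parse_path, bundle.occ_path, bundle.last_path):
        if not path.exists():
            raise BundleFormatError(f"missing bundle file {path}")

    phrases = _split_dict_file(bundle.dict_path.read_bytes())

    raw_parse = bundle.parse_path.read_bytes()
    if len(raw_parse) % 4:
        raise BundleFormatError("parse file length is not a multiple of 4 (truncated)")
    ranks = np.frombuffer(raw_parse, dtype="<u4").astype(np.int64)

    raw_occ = bundle.occ_path.read_bytes()
    if len(raw_occ) % 4:
        raise BundleFormatError("occ file length is not a multiple of 4 (truncated)")
    freqs = np.frombuffer(raw_occ, dtype="<u4").astype(np.int64)
    if len(freqs) != len(phrases):
        raise BundleFormatError(
            f"occ file has {len(freqs)} entries for {len(phrases)} phrases"
        )

    if len(ranks) and int(ranks.max()) >= len(phrases):
        raise BundleFormatError(
            f"parse rank {int(ranks.max())} out of range for {len(phrases)} phrases"
        )
    hist = np.bincount(ranks, minlength=len(phrases))
    if not np.array_equal(hist, freqs):
        raise BundleFormatError("parse/occ frequency mismatch")

    last_raw = _last_from_disk(bundle.last_path.read_bytes())
    if len(last_raw) != len(ranks):
        raise BundleFormatError(
            f"last file has {len(last_raw)} bytes for {len(ranks)} parse entries"
        )
    return (
        Dictionary(phrases=phrases, freqs=freqs),
        ParseArray(ranks),
        LastArray(last_raw),
    )


def read_metadata(src) -> dict:
    bundle = ArtifactBundle.at(src)
    if bundle.meta_path.exists():
        return json.loads(bundle.meta_path.read_text())
    return {}


def write_result(result: ParseResult, dest, policy: str | None = None) -> ArtifactBundle:
    return write_bundle(
        result.dictionary, result.parse, result.last, dest, w=result.w, policy=policy
    )


# ---------------------------------------------------------------------------
# input readers and BWT writers


def load_input(
    path,
    fasta: bool | None = None,
    filter_dna: bool = False,
    sep: bytes | None = None,
) -> bytes:
    """Read a raw-text or FASTA input file into a byte string.

    FASTA records are concatenated in file order; ``sep`` optionally inserts
    a separator symbol between records. ``filter_dna`` uppercases and keeps
    only the symbols A, C, G, T and N. In raw mode a single trailing newline
    is stripped.
    """
    path = Path(path)
    if fasta is None:
        fasta = path.suffix.lower() in (".fa", ".fasta", ".fna", ".ffn")
    if fasta:
        from Bio import SeqIO

        parts = []
        for record in SeqIO.parse(str(path), "fasta"):
            parts.append(str(record.seq).encode())
        if sep:
            text = sep.join(parts)
        else:
            text = b"".join(parts)
    else:
        text = path.read_bytes()
        if text.endswith(b"\n"):
            text = text[:-1]
    if filter_dna:
        text = bytes(b for b in text.upper() if b in b"ACGTN")
    if not text:
        raise InputError(f"no input symbols read from {path}")
    return text


def bwt_to_text(bwt: bytes) -> str:
    """Human-readable BWT with the terminator rendered as ``$``."""
    return bwt.replace(bytes([SENTINEL_DOLLAR]), b"$").decode("latin-1")


def write_bwt(bwt: bytes, path, text_mode: bool = False) -> None:
    """Write a BWT: raw bytes with terminator 0x00, or text with ``$``."""
    path = Path(path)
    if text_mode:
        path.write_text(bwt_to_text(bwt) + "\n")
    else:
        path.write_bytes(bwt.replace(bytes([SENTINEL_DOLLAR]), bytes([_DISK_DOLLAR])))


def read_bwt(path, text_mode: bool = False) -> bytes:
    """Inverse of :func:`write_bwt`."""
    path = Path(path)
    if text_mode:
        raw = path.read_text()
        if raw.endswith("\n"):
            raw = raw[:-1]
        return raw.encode("latin-1").replace(b"$", bytes([SENTINEL_DOLLAR]))
    return path.read_bytes().replace(bytes([_DISK_DOLLAR]), bytes([SENTINEL_DOLLAR]))
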