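"""Exception hierarchy.

Two top-level families matter for the CLI exit-code contract: problems with
what the user handed us (:class:`InputError`, exit code 2) and violations of
internal invariants that indicate a bug or corrupted artifact
(:class:`InternalConsistencyError`, exit code 3).
"""


class PfpError(Exception):
    """Base class for all package errors."""


class InputError(PfpError):
    """The input text, pattern, file or parameter set is invalid."""


class SentinelInInputError(InputError):
    """The input text contains a reserved sentinel byte."""

    def __init__(self, position: int, byte: int):
        self.position = position
        self.byte = byte
        super().__init__(
            f"reserved sentinel byte 0x{byte:02x} found in input at position {position}"
        )


class BundleFormatError(InputError):
    """An on-disk artifact bundle is truncated or mutually inconsistent."""


class InternalConsistencyError(PfpError):
    """An internal invariant was violated (bug or corrupted artifact)."""


class FingerprintCollisionError(InternalConsistencyError):
    """Two distinct phrases produced the same fingerprint.

    No recovery is attempted: the parse is aborted.
    """
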