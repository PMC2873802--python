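"""Exception hierarchy shared across the package.

Validation never raises -- :func:`lrgkit.core_model.validate_record` reports
findings.  Exceptions are reserved for operations whose contract cannot be
satisfied (out-of-span coordinates, unmappable bases, malformed input text).
"""

from __future__ import annotations


class LrgError(ValueError):
    """Base class for all domain errors."""


class InvalidRecordError(LrgError):
    """A record failed an invariant required by the requested operation."""


class OutOfSpanError(LrgError):
    """A position falls outside the interval an operation is defined on."""


class NonCodingTranscriptError(LrgError):
    """Coding (c.) coordinates requested on a transcript without a CDS."""


class UnmappablePositionError(LrgError):
    """A position has no counterpart under a mapping (gap or insertion).

    ``flanks`` carries the nearest mapped positions on either side when the
    position is interrupted by a sequence difference, as ``(left, right)``
    with ``None`` for a missing side.
    """

    def __init__(self, message: str, flanks: tuple | None = None):
        super().__init__(message)
        self.flanks = flanks


class OffsetConventionError(LrgError):
    """An intron offset crosses the midpoint into the other boundary's half."""


class RefMismatchError(LrgError):
    """Stated reference base disagrees with the record sequence."""

    code = "REF_MISMATCH"


class HgvsParseError(LrgError):
    """Malformed variant description; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class DeprecatedIvsError(HgvsParseError):
    """IVS-style intron notation; convert with ``ivs_to_c`` instead."""

    def __init__(self, text: str):
        super().__init__(
            f"deprecated IVS notation {text!r}: convert with ivs_to_c "
            "against an explicit transcript",
            0,
        )


class UnknownFrameError(LrgError):
    """Requested reference frame is not declared by the record."""
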