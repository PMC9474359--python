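"""Exception hierarchy for etmorph.

All errors raised by the library derive from :class:`EtmorphError` so callers
(and the CLI) can catch the package's failures in one clause.
"""


class EtmorphError(Exception):
    """Base class for all etmorph errors."""


class GeometryError(EtmorphError, ValueError):
    """Degenerate geometric input (collinear points, zero-length segment, ...)."""


class ValidationError(EtmorphError, ValueError):
    """Structurally invalid value (non-orthonormal rotation, bad preset field, ...)."""


class MissingLandmarkError(EtmorphError, KeyError):
    """A landmark required by a plane or measurement is absent from the set."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ParseError(EtmorphError, ValueError):
    """Malformed input file; message carries the offending row/line where known."""


class PresetError(EtmorphError, KeyError):
    """Unknown cohort preset name."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class GenerationError(EtmorphError, RuntimeError):
    """Synthetic-subject generation could not satisfy its geometric constraints."""
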