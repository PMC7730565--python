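"""Exception hierarchy for physioqc.

All exceptions derive from :class:`PhysioQCError` so callers can catch the
package's failures with a single clause; the subclasses map onto the distinct
failure modes of the pipeline (bad arguments, degenerate signals, not enough
data, malformed input files).
"""


class PhysioQCError(Exception):
    """Base class for all physioqc errors."""


class InvalidArgumentError(PhysioQCError, ValueError):
    """An argument violates a precondition (e.g. cutoff beyond Nyquist)."""


class DegenerateSignalError(PhysioQCError):
    """A computation is undefined on this signal (e.g. constant segment)."""


class InsufficientDataError(PhysioQCError):
    """Not enough samples/beats to compute the requested quantity."""

    def __init__(self, what: str, detail: str = ""):
        self.what = what
        msg = f"insufficient data for {what}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class UndefinedRatioError(PhysioQCError):
    """A ratio's denominator is below machine tolerance."""


class MalformedInputError(PhysioQCError):
    """An input file does not satisfy the expected format."""
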