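"""Exception hierarchy.

All errors raised intentionally by the package derive from :class:`GaitrelError`
so callers (and the CLI) can separate bad input from internal failure.
"""


class GaitrelError(Exception):
    """Base class for all expected gaitrel errors."""


class FormatError(GaitrelError):
    """A file could not be parsed as the format it claims to be."""


class ManifestError(GaitrelError):
    """A study manifest is invalid or inconsistent with its design."""


class NoCompleteCycleError(GaitrelError):
    """Fewer than two heel strikes detected: no complete gait cycle."""


class GapError(GaitrelError):
    """Missing samples overlap a region the computation needs."""


class ValidationError(GaitrelError):
    """A domain-type invariant was violated."""
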