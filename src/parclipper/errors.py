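"""Exception hierarchy.

``ParclipError`` marks user-facing failures (bad input, degenerate data);
anything else escaping the library is an internal error.
"""


class ParclipError(Exception):
    """Base class for user-facing errors."""


class IngestError(ParclipError):
    """Problem reading alignments or the reference genome."""


class ModelError(ParclipError):
    """Mixture model cannot be fitted or evaluated."""


class MrnError(ParclipError):
    """Mini-Rank-Norm boundary search cannot proceed."""


class FdrError(ParclipError):
    """FDR estimation cannot proceed."""
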