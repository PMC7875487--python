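"""Exception hierarchy for knockscope.

All package-specific errors derive from :class:`KnockscopeError` so callers can
catch everything with one clause; most also derive from ``ValueError`` because
they signal bad inputs.
"""


class KnockscopeError(Exception):
    """Base class for all knockscope errors."""


class ParameterError(KnockscopeError, ValueError):
    """A parameter is out of its valid range or a required input is missing."""


class FormatError(KnockscopeError, ValueError):
    """A file on disk does not conform to the expected layout."""


class PlacementError(KnockscopeError, RuntimeError):
    """ROI placement failed: a compartment cannot hold the requested boxes."""


class DegenerateInputError(KnockscopeError, ValueError):
    """Input is degenerate for the requested statistic (e.g. constant image,
    zero denominator, non-positive whole-cell fluorescence)."""


class ValidationError(KnockscopeError, ValueError):
    """A record set violates a structural invariant (ordering, pairing...)."""
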