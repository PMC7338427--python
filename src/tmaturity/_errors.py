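"""Exception hierarchy shared across the package."""


class TMaturityError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TMaturityError):
    """Invalid preset, panel, spillover or run configuration."""


class FormatError(TMaturityError):
    """Malformed FCS or CSV event file."""


class MarkerLookupError(TMaturityError, KeyError):
    """A marker is absent from (or ambiguous in) a tube."""


class InsufficientEventsError(TMaturityError):
    """Too few events in the primary gate to estimate thresholds."""


class NumericError(TMaturityError):
    """Singular spillover matrix or other numerical failure."""


class MergeError(TMaturityError):
    """Conflicting subset entries while merging per-tube results."""


class DataError(TMaturityError):
    """Inconsistent event data or labels at pipeline runtime."""
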