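"""Exception hierarchy.

All package errors derive from :class:`RecurcorError` so callers can catch a
single type; the three subclasses distinguish configuration problems (bad
thresholds, too few datasets), malformed input files, and record-level data
problems respectively.
"""


class RecurcorError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(RecurcorError, ValueError):
    """Invalid run configuration (thresholds, dataset counts, grids)."""


class FormatError(RecurcorError, ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(RecurcorError, ValueError):
    """Input records violate a data invariant (non-numeric AUC, duplicate
    conflicting class assignments, missing annotations, ...)."""
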