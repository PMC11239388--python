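"""Exception hierarchy for mrkit.

All package-specific errors derive from :class:`MrKitError` so callers can
catch everything the pipeline may raise with a single except clause.
"""


class MrKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrKitError):
    """A column mapping, config file, or parameter set is unusable."""


class InputError(MrKitError):
    """An input file or table is empty or structurally unreadable."""


class NoInstrumentsError(MrKitError):
    """Instrument selection produced an empty set; estimation cannot proceed."""


class NoOverlapError(MrKitError):
    """Exposure and outcome tables share no variant identifiers."""


class InsufficientInstrumentsError(MrKitError):
    """An estimator received fewer variant pairs than it requires."""
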