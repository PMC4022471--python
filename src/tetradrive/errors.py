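"""Exception hierarchy for tetradrive.

Configuration problems (bad allele references, malformed cross specs) are kept
distinct from runtime problems (unsupported sizes, degenerate inputs) so the
command-line layer can map them to different exit codes.
"""


class TetradriveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TetradriveError, ValueError):
    """A cross specification or config file is internally inconsistent."""


class ParameterError(TetradriveError, ValueError):
    """A numeric parameter is outside its admissible range."""


class EnumerationSizeError(TetradriveError, ValueError):
    """Exact enumeration was requested for a cross that is too large."""


class MaskedLocusError(TetradriveError, ValueError):
    """An estimator was asked for a locus whose killing signal is masked
    or absent, so the ascus-class counts are uninformative for it."""
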