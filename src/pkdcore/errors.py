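"""Exception hierarchy shared by all pkdcore modules."""


class PkdcoreError(Exception):
    """Base class for all pkdcore errors."""


class FormatError(PkdcoreError, ValueError):
    """A file does not conform to its declared table format."""


class MetadataError(PkdcoreError, ValueError):
    """Sample metadata is inconsistent with the data it describes."""


class ParameterError(PkdcoreError, ValueError):
    """A configuration or simulation parameter is out of its valid range."""


class NormalizationError(PkdcoreError, ValueError):
    """Size-factor normalization cannot be computed for this matrix."""


class AnalysisError(PkdcoreError, ValueError):
    """An analysis stage received inputs violating its preconditions."""


class ConfigError(PkdcoreError, ValueError):
    """A run configuration file or flag combination is invalid."""
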