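"""Exception hierarchy shared across the pipeline stages."""


class DesmoproxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DesmoproxError):
    """A configuration value violates its invariant; names the offending field."""


class SchemaError(DesmoproxError):
    """An input table is missing a required column or sample."""


class FormatError(DesmoproxError):
    """An input table is malformed (e.g. duplicate protein IDs)."""


class NormalizationError(DesmoproxError):
    """Normalization preconditions violated (e.g. an all-missing sample)."""


class DesignError(DesmoproxError):
    """The sample design lacks a group required for scoring."""


class MappingError(DesmoproxError):
    """Ortholog mapping cannot proceed (e.g. empty mapping table)."""


class ParameterError(DesmoproxError):
    """An analysis parameter is out of range (e.g. k > number of profiles)."""


class InputError(DesmoproxError):
    """A user-supplied list or table is unusable (e.g. empty external list)."""


class GeometryError(DesmoproxError):
    """Invalid geometry input (e.g. an open membrane trace)."""


class StatisticsError(DesmoproxError):
    """Too little data for the requested statistical procedure."""
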