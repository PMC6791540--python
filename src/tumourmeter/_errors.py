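"""Exception hierarchy shared by all tumourmeter modules.

CLI exit-code mapping: ConfigurationError -> 2, DataError -> 3,
anything else under TumourmeterError -> 4.
"""


class TumourmeterError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TumourmeterError):
    """Invalid parameter values, unknown presets, malformed configs."""


class GeometryError(ConfigurationError):
    """Lattice dimensions cannot accommodate the requested seed geometry."""


class BoundaryError(TumourmeterError):
    """Tumour reached the lateral or top lattice boundary during growth."""


class MeasurementError(TumourmeterError):
    """Virtual measurement requested on an empty lattice."""


class UndefinedMetricError(TumourmeterError):
    """Efficacy metric undefined (zero baseline or zero control AUC)."""


class DataError(TumourmeterError):
    """Tabular input cannot be read or validated."""


class SchemaError(DataError):
    """A schema map references columns missing from the file."""
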