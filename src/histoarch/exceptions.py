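"""Exception types raised by histoarch."""


class HistoarchError(Exception):
    """Base class for all histoarch errors."""


class SchemaError(HistoarchError):
    """An input table is missing a mandatory column or has an unparsable field."""


class IntegrityError(HistoarchError):
    """An input violates a data invariant (e.g. duplicate cell ids)."""


class ConfigError(HistoarchError):
    """A configuration value is invalid or inconsistent."""
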