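"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is missing, malformed, or out of range.

    The message always names the offending field.
    """


class MappingError(ValueError):
    """A raw claims code could not be resolved to a category."""


class SchemaError(ValueError):
    """An input table does not conform to the documented schema."""
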