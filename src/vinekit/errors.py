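"""Exception hierarchy shared across the package."""


class VinekitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VinekitError):
    """A file did not conform to the expected external format."""


class ConfigError(VinekitError):
    """An invalid parameter, rule or simulation configuration."""
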