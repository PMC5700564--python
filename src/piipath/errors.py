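"""Exception hierarchy."""


class PiipathError(Exception):
    """Base class for package errors."""


class ConfigurationError(PiipathError):
    """A configuration value or column mapping is invalid."""


class DataError(PiipathError):
    """Input data violate a structural precondition."""


class WindowSelectionError(PiipathError):
    """No suitable smoothing window could be chosen from the ACF."""
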