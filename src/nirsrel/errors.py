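"""Exception hierarchy used across the package."""


class NirsrelError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NirsrelError):
    """A configuration value is invalid or internally inconsistent."""


class InputError(NirsrelError):
    """Input data violate a precondition (wrong shape, range, or schema)."""


class EstimationError(NirsrelError):
    """A model fit cannot be carried out (e.g. rank-deficient design)."""
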