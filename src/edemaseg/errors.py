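"""Exception hierarchy shared by all stages."""


class EdemasegError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EdemasegError):
    """A configuration file or parameter set failed validation."""


class DataError(EdemasegError):
    """Input data violated a contract (shape, value range, geometry)."""


class ValidationError(DataError):
    """A domain object failed its invariants."""


class AlignmentError(DataError):
    """Two grids that must share a voxel lattice do not."""


class FormatError(DataError):
    """File content is inconsistent with the declared format."""


class UnsupportedFormatError(DataError):
    """The requested on-disk format is not writable/readable here."""
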