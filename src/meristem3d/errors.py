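"""Exception hierarchy shared across the package."""


class MeristemError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MeristemError):
    """An on-disk artifact has the wrong format (e.g. float-typed label TIFF)."""


class InputError(MeristemError):
    """An in-memory input violates a precondition (e.g. empty cell set)."""


class ParameterError(MeristemError):
    """A user-supplied parameter or cell selection is invalid."""


class ConsistencyError(MeristemError):
    """Two inputs that must agree on cell labels do not."""


class ConfigError(MeristemError):
    """A pipeline configuration is malformed or stages are mis-ordered."""


class DegenerateGeometryError(MeristemError):
    """A geometric query is undefined (e.g. zero-length cone axis)."""
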