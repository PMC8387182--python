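"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes: configuration problems exit
with 2, data/format problems with 3 and numerical failures with 4.
"""


class AsdmetryError(Exception):
    """Base class for all package errors."""


class ConfigError(AsdmetryError):
    """Invalid configuration value (bad angular step, unstable time step, ...)."""

    exit_code = 2


class GeometryError(ConfigError):
    """Phantom geometry is inconsistent (e.g. defect larger than the septum)."""


class FormatError(AsdmetryError):
    """A file does not conform to the expected on-disk format."""

    exit_code = 3


class NumericalError(AsdmetryError):
    """A numerical scheme produced non-finite values."""

    exit_code = 4
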