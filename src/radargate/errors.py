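"""Exception taxonomy.

Each error class maps to one failure mode a screening run can hit:
bad files, bad configuration, bad geometry, bad numbers, bad inputs.
The CLI translates these into distinct exit codes.
"""


class RadargateError(Exception):
    """Base class for all radargate errors."""


class FormatError(RadargateError):
    """Unreadable, truncated, or unsupported FCS file."""


class ConfigurationError(RadargateError):
    """Panel / channel / parameter mismatch between inputs."""


class MergeError(RadargateError):
    """Event sets cannot be merged (conflicting marker maps)."""


class GeometryError(RadargateError):
    """Invalid gate geometry (e.g. self-intersecting polygon)."""


class InputError(RadargateError):
    """Data does not satisfy an operation's preconditions."""


class NumericalError(RadargateError):
    """Numerical failure (e.g. singular spillover matrix)."""


class TemplateError(RadargateError):
    """Screening-template schema or invariant violation."""
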