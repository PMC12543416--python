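"""Exception hierarchy.

Errors map onto CLI exit codes: :class:`InputError` -> 1,
:class:`ConfigError` -> 2.
"""


class CagetrackError(Exception):
    """Base class for all cagetrack errors."""


class InputError(CagetrackError):
    """Invalid data passed to an operation (bad values, mismatched views,
    malformed files)."""


class SchemaError(InputError):
    """A detection-stream or revolutions file does not conform to the
    documented column schema."""


class ConfigError(CagetrackError):
    """Invalid configuration (non-positive tolerance, bad transition
    matrix, overlapping phase windows, missing static regions...)."""
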