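"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``InputError`` (and its
subclasses) to exit code 3.
"""


class G4StratError(Exception):
    """Base class for all package errors."""


class ConfigError(G4StratError):
    """Invalid or inconsistent configuration/parameters."""


class InputError(G4StratError):
    """Malformed or out-of-contract input data."""


class DomainError(InputError):
    """A value lies outside the domain its score kind allows."""


class PackingError(ConfigError):
    """Synthetic genome too short to hold the requested motif library."""
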