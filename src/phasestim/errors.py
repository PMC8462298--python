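"""Exception hierarchy shared across the package.

Exit-code mapping in the CLI: ConfigError -> 2, DataError -> 3.
"""


class PhasestimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhasestimError):
    """Invalid configuration: bad parameter value, schema violation, Nyquist
    violation, mismatched sample rates."""


class DataError(PhasestimError):
    """Invalid or inconsistent data file: malformed signal file, missing
    header, non-uniform time base, log/plan mismatch."""
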