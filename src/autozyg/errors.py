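"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, everything else
derived from AutozygError -> 3.
"""


class AutozygError(Exception):
    """Base class for all errors raised by autozyg."""


class ConfigError(AutozygError):
    """Invalid run/simulation configuration."""


class FormatError(AutozygError):
    """Malformed input file (PED/MAP, BED, pedigree table)."""


class PedigreeError(AutozygError):
    """Structurally invalid pedigree (cycles, duplicate records)."""


class DataError(AutozygError):
    """Semantically invalid data (misaligned matrices, empty panels, ...)."""
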