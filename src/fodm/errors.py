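"""Exception hierarchy for the hydrophobicity-field pipeline."""


class FodmError(Exception):
    """Base class for all package errors."""


class FormatError(FodmError):
    """Structure file could not be parsed under the named standard."""


class EmptyStructureError(FodmError):
    """Parsed file contains no protein residues."""


class UnknownResidueError(FodmError):
    """Residue name absent from the active hydrophobicity scale."""


class DegenerateGeometryError(FodmError):
    """All points coincide; no orientation or Gaussian can be defined."""


class DegenerateProfileError(FodmError):
    """Observed profile is identically zero (no interactions within cutoff)."""


class SupportError(FodmError):
    """KL divergence undefined: p has mass where q is zero."""


class UndefinedRDError(FodmError):
    """Both divergences are zero (O = T = R); RD is 0/0."""


class SelectionError(FodmError):
    """Unit selection does not resolve against the structure."""


class ConfigError(FodmError):
    """Run configuration file is invalid; message names the field."""
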