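"""Exception types shared across the pipeline stages."""


class NeovaxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeovaxError, ValueError):
    """Invalid generator or pipeline configuration."""


class InputError(NeovaxError, ValueError):
    """Inputs violate a stage precondition (unknown target, bad partition size...)."""


class ReferenceMismatchError(NeovaxError, ValueError):
    """A variant's stated reference residue disagrees with the protein sequence."""


class ValidationError(NeovaxError, ValueError):
    """Malformed peptide or HLA allele name."""


class AssemblyError(NeovaxError, ValueError):
    """Construct assembly failed (non-standard residue in a target)."""


class AssayError(NeovaxError, ValueError):
    """An assay record is unusable (non-positive control, failed positive control)."""


class ParseError(NeovaxError, ValueError):
    """A patient input file could not be parsed; message names file and record."""
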