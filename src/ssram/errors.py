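"""Exception hierarchy.

All data/model errors raised by the package derive from :class:`SsramError`
so the CLI can map them to a nonzero exit code distinct from usage errors.
"""


class SsramError(Exception):
    """Base class for all data and model errors."""


class PedigreeError(SsramError):
    """Invalid pedigree: cycles, unknown parent labels, duplicates."""


class DesignError(SsramError):
    """Invalid model design: rank-deficient X, misaligned labels."""


class MatrixError(SsramError):
    """Invalid matrix input: asymmetry, label mismatch, singularity."""


class SolverError(SsramError):
    """Linear solver failure: singular system or non-convergence."""


class FormatError(SsramError):
    """Malformed input file."""
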