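"""Exception hierarchy shared across the package.

Every pipeline stage raises a subclass of :class:`IrgpiError` so that the
command-line layer can map failures to exit codes and name the stage that
produced them.
"""


class IrgpiError(Exception):
    """Base class for all package errors."""


class FormatError(IrgpiError):
    """A file could not be parsed in the declared format."""


class EmptyInputError(IrgpiError):
    """An input contained no usable rows/columns/samples."""


class ValidationError(IrgpiError):
    """A domain object violated one of its invariants."""


class MissingGeneError(IrgpiError):
    """A gene required by a pair or signature is absent from the matrix."""

    def __init__(self, genes):
        self.genes = sorted(set(genes))
        super().__init__(f"gene(s) not found in expression matrix: {', '.join(self.genes)}")


class EmptyCandidateError(IrgpiError):
    """No candidate genes/pairs survived a filtering stage."""


class ParameterError(IrgpiError):
    """A numeric parameter was outside its admissible range."""


class EmptySignatureError(IrgpiError):
    """Model selection retained no pairs; no signature can be built."""


class ConvergenceError(IrgpiError):
    """An iterative fit failed to converge; carries diagnostics."""
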