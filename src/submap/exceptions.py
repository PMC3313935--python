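"""Exception hierarchy.

``SubmapError`` covers user-facing validation problems (bad input files,
inconsistent parameters); ``NumericalError`` covers breakdowns of the
numerics (non-finite likelihoods, underflowing transition probabilities).
The CLI maps these onto distinct exit codes.
"""


class SubmapError(Exception):
    """Base class for all validation and data errors."""


class NewickError(SubmapError):
    """Malformed Newick input, duplicate labels, or missing branch lengths."""


class AlignmentError(SubmapError):
    """Ragged alignments, frame violations, in-frame stop codons."""


class ParameterError(SubmapError):
    """Model or estimator parameters outside their admissible range."""


class NumericalError(Exception):
    """Numerical failure: non-finite likelihood, underflow, divergence."""
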