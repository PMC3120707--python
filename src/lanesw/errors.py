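"""Exception hierarchy shared across the package."""


class LaneSWError(Exception):
    """Base class for all lanesw errors."""


class ParameterError(LaneSWError, ValueError):
    """An argument violates its documented precondition."""


class MatrixParseError(LaneSWError, ValueError):
    """A substitution-matrix file is malformed."""


class EncodingError(LaneSWError, ValueError):
    """A sequence character cannot be encoded as a residue code."""


class FormatError(LaneSWError, ValueError):
    """A sequence file (FASTA or binary) is malformed or inconsistent."""
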