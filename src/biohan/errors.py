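"""Exception hierarchy shared across the package."""


class BioHANError(Exception):
    """Base class for all package errors."""


class FormatError(BioHANError):
    """An input file could not be parsed in the declared serialization."""


class ConfigurationError(BioHANError):
    """An invalid option, dimension chain, or missing configuration."""


class MalformedAlignmentError(BioHANError):
    """An alignment file violates the OAEI Alignment Format contract."""


class ValidationError(BioHANError):
    """A value violates a domain-type invariant (e.g. score outside [0, 1])."""


class MalformedCollectionError(BioHANError):
    """An rdf:List is cyclic or otherwise not a well-formed collection."""


class ConsistencyError(BioHANError):
    """Cross-structure references do not line up (e.g. dangling anchors)."""


class NumericError(BioHANError):
    """A numeric precondition failed (non-finite input, point outside ball)."""


class DivergenceError(BioHANError):
    """Training produced a non-finite loss."""
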