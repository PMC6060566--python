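"""Exception hierarchy shared by all ssosort modules."""


class SSOSortError(Exception):
    """Base class for every error raised by ssosort."""


class ParseError(SSOSortError, ValueError):
    """Malformed permutation or operation text."""


class SizeError(SSOSortError, ValueError):
    """Two objects that must have equal length do not."""


class PositionError(SSOSortError, ValueError):
    """An operation's positions are out of range or violate its index pattern."""


class TopologyError(SSOSortError, ValueError):
    """A linear permutation was given where a circular one is required, or vice versa."""


class ModelError(SSOSortError, ValueError):
    """An operation is not allowed under the current model (e.g. sign flips on unsigned input)."""


class ValidityError(SSOSortError, ValueError):
    """A displacement vector is not valid for the permutation at hand."""


class SequenceError(SSOSortError, ValueError):
    """An operation sequence does not sort its origin permutation."""


class CapacityError(SSOSortError, ValueError):
    """A brute-force computation was requested beyond its configured state-space bound."""
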