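"""Exception hierarchy for regcn."""


class RegcnError(Exception):
    """Base class for all regcn errors."""


class InputError(RegcnError):
    """Unreadable or malformed input file."""


class ParseError(InputError):
    """A specific line of an input file could not be parsed."""


class ShapeError(RegcnError):
    """Matrix/vector dimensions inconsistent with the graph."""


class ParameterError(RegcnError):
    """A parameter violates its documented constraints."""


class SupervisionError(RegcnError):
    """The pseudo-labeled supervision set is unusable (e.g. an empty
    community)."""
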