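"""Exception hierarchy for sigcircuits.

All errors raised by the package derive from :class:`SigCircuitsError` so
callers can catch everything from one base class.
"""


class SigCircuitsError(Exception):
    """Base class for all sigcircuits errors."""


class FormatError(SigCircuitsError):
    """A tabular input is malformed (missing column, unknown token, bad value)."""


class IntegrityError(SigCircuitsError):
    """An input violates a referential or structural constraint
    (edge to an unknown node, self-loop, conflicting duplicate edges)."""


class StructuralError(SigCircuitsError):
    """A pathway graph has no usable receptor/effector structure."""


class InputError(SigCircuitsError):
    """Arguments to an analysis operation are invalid (empty group,
    mismatched shapes, out-of-range values)."""
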