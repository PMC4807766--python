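"""Exception hierarchy.

ValidationError maps to CLI exit code 2 (bad input), ComputationError to
exit code 1 (a stage failed on valid input).
"""


class ScenosetError(Exception):
    """Base class for all package errors."""


class ValidationError(ScenosetError):
    """Input violated a documented precondition or invariant."""


class ComputationError(ScenosetError):
    """A computation failed on otherwise valid input."""
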