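"""Exception hierarchy shared across the package.

Every error a caller is expected to branch on has its own class; the CLI
maps them onto exit codes (bad input -> 1, cap exceeded -> 3).
"""


class BoolmergeError(Exception):
    """Base class for all package errors."""


class RuleSyntaxError(BoolmergeError, ValueError):
    """Malformed rule string; carries the 0-based offset of the problem."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MissingVariableError(BoolmergeError, KeyError):
    """An assignment does not cover a regulator needed for evaluation."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"assignment does not define regulator {self.name!r}"


class CapExceededError(BoolmergeError):
    """A state-space or support-size cap was exceeded."""


class ModelFormatError(BoolmergeError, ValueError):
    """Unreadable or unsupported model file (bad .bnet line, non-Boolean SBML...)."""


class UnsupportedModelError(ModelFormatError):
    """Model is syntactically fine but outside scope (e.g. multi-valued)."""


class StandardizationError(BoolmergeError, ValueError):
    """Symbol standardization produced a collision that needs manual curation."""


class MergeError(BoolmergeError, ValueError):
    """Invalid merge request (too few models, unknown override symbol...)."""


class DegenerateVarianceError(BoolmergeError, ValueError):
    """Correlation requested on a constant vector."""
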