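"""Exception hierarchy for the molprobe pipeline.

All molprobe-specific failures derive from :class:`MolprobeError` so callers
can catch the whole family with one clause; argument-validation failures
additionally derive from :class:`ValueError` where that is the natural
builtin.
"""


class MolprobeError(Exception):
    """Base class for all molprobe errors."""


class SmilesParseError(MolprobeError, ValueError):
    """A string could not be parsed as SMILES; carries the offending text."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"invalid SMILES: {smiles!r}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class SmartsPatternError(MolprobeError, ValueError):
    """A SMARTS pattern failed to compile."""


class TokenizationError(MolprobeError, ValueError):
    """Input text could not be split into SMILES tokens."""


class ConfigurationError(MolprobeError, ValueError):
    """A generator/rule configuration is invalid."""


class GenerationExhaustedError(MolprobeError, RuntimeError):
    """The molecule generator could not produce enough distinct valid
    molecules within its retry budget."""


class EnumerationExhaustedError(MolprobeError, RuntimeError):
    """Too few distinct non-canonical renderings exist for a molecule."""


class DegenerateRangeError(MolprobeError, ValueError):
    """A property value range has zero width and cannot be segmented."""


class StratificationError(MolprobeError, ValueError):
    """A class has too few members for the requested number of folds."""


class JsonlFormatError(MolprobeError, ValueError):
    """A prompt-completion JSONL line is malformed; carries the line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class TrainingError(MolprobeError, RuntimeError):
    """A backend could not be fitted (e.g. empty or fully-dropped data)."""


class NoMatchError(MolprobeError, ValueError):
    """A SMARTS group has no match in the molecule being probed."""
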