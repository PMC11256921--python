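"""Exception hierarchy shared across the package."""


class MoltextError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(MoltextError):
    """A SMILES string could not be parsed into a molecule."""


class ValenceError(MoltextError):
    """A molecule failed valence/sanitization checks."""


class ConformerError(MoltextError):
    """3D embedding failed after the bounded number of attempts."""

    def __init__(self, message: str, attempts: int = 0):
        super().__init__(message)
        self.attempts = attempts


class FormatError(MoltextError):
    """A chemical file (SDF/MOL) was malformed or unreadable."""


class ConfigError(MoltextError):
    """Inconsistent configuration (e.g. parameter dimension mismatch)."""


class StateError(MoltextError):
    """An operation needs state the object lacks (e.g. 3D coordinates)."""


class AugmentationInfeasibleError(MoltextError):
    """No chemically valid augmentation exists for this molecule/kind."""


class PromptError(MoltextError):
    """Unknown molecule-editing prompt identifier."""
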