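"""Exception hierarchy."""


class GexmolError(Exception):
    """Base class for package errors."""


class ConfigurationError(GexmolError):
    """Invalid or unknown configuration value."""


class SmilesParseError(GexmolError):
    """A SMILES string could not be parsed under the grammar."""

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class DerivationError(GexmolError):
    """A rule sequence is not a consistent leftmost derivation."""


class EncodingError(GexmolError):
    """Input contains tokens outside the model vocabulary."""


class ShapeError(GexmolError):
    """Tensor dimensions do not match the configured model."""
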