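"""Exception hierarchy shared across the pipeline stages."""


class LarynxCadError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(LarynxCadError):
    """A phantom specification violates its geometric or intensity invariants."""


class FormatError(LarynxCadError):
    """An input file or directory does not match the expected layout."""


class DegenerateInputError(LarynxCadError):
    """An image is degenerate for the requested operation (e.g. constant for Otsu)."""


class NoCandidateError(LarynxCadError):
    """No region survives the glottal structure screening."""


class DegenerateContourError(LarynxCadError):
    """An active contour collapsed below a usable vertex count."""


class TrainingError(LarynxCadError):
    """Classifier training failed (e.g. a tree node received a single class)."""
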