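"""Exception hierarchy for gepmi."""


class GepmiError(Exception):
    """Base class for all gepmi-specific errors."""


class SketchCompatibilityError(GepmiError, ValueError):
    """Two sketches differ in k, n or hash seed and cannot be compared."""


class UndefinedSimilarityError(GepmiError, ValueError):
    """Similarity is undefined (e.g. both sketches empty)."""


class InsufficientDataError(GepmiError, ValueError):
    """Too few values to fit a null distribution."""


class DegenerateDataError(GepmiError, ValueError):
    """Values have zero variance; no continuous null can be fitted."""


class ModelSelectionError(GepmiError, ValueError):
    """Every candidate family failed to fit."""


class EvaluationError(GepmiError, ValueError):
    """Scores cannot be evaluated (e.g. only one class present)."""
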