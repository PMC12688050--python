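"""Named exceptions raised across the package.

Load-time validation failures get distinct types so callers can tell a
malformed catalog from a malformed lexicon, and tests can assert on the
exact failure mode rather than on message text.
"""


class ExcurvesError(Exception):
    """Base class for all package errors."""


class CatalogLoadError(ExcurvesError):
    """Catalog file missing or structurally invalid."""


class DuplicateTopicError(CatalogLoadError):
    """Two topics share an id."""


class DanglingCategoryError(CatalogLoadError):
    """A topic references a category id that does not exist."""


class LexiconLoadError(ExcurvesError):
    """Lexicon file missing or structurally invalid."""


class SynonymCollisionError(LexiconLoadError):
    """The same normalized synonym maps to two different concepts."""


class CrosswalkError(ExcurvesError):
    """Crosswalk references unknown concepts/topics or is not total."""


class ValidationError(ExcurvesError):
    """Tabular input fails a referential or range check."""


class CalibrationError(ExcurvesError):
    """Power-law calibration could not meet its bucket targets.

    Carries the best exponent found so a caller can inspect how close
    the search got.
    """

    def __init__(self, message: str, best_exponent: float, best_error: float):
        super().__init__(message)
        self.best_exponent = best_exponent
        self.best_error = best_error


class GenerationError(ExcurvesError):
    """Synthetic note rendering hit an unrepresentable mention."""


class UndefinedGiniError(ExcurvesError):
    """Gini requested on an all-zero vector."""


class UndefinedKappaError(ExcurvesError):
    """Cohen's kappa undefined because chance agreement is 1."""
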