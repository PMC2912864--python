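"""Exception hierarchy shared across the package."""


class SnpMdrError(Exception):
    """Base class for all package errors."""


class CohortFormatError(SnpMdrError, ValueError):
    """A delimited or VCF input could not be parsed into a cohort."""


class CohortIntegrityError(SnpMdrError, ValueError):
    """Parsed data violates a structural invariant (duplicate ids, mismatched panels, ...)."""


class UnknownSnpError(SnpMdrError, KeyError):
    """An rsid was requested that is not in the cohort's panel."""


class ConfigError(SnpMdrError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class DegenerateTableError(SnpMdrError, ValueError):
    """A contingency table has a zero margin or is otherwise unusable."""


class UndefinedOddsRatioError(SnpMdrError, ValueError):
    """The 2x2 table has two zero cells in one row or column; no finite OR exists."""


class SeparationError(SnpMdrError, RuntimeError):
    """Logistic regression failed to converge (complete or quasi-separation)."""


class NoComparableCellsError(SnpMdrError, ValueError):
    """Concordance is undefined: no cell is non-missing in both cohorts."""


class EvaluationError(SnpMdrError, ValueError):
    """A classifier could not be evaluated (no evaluable case or control)."""
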