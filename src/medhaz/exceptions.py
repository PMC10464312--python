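"""Exception hierarchy for the medhaz pipeline."""


class MedhazError(Exception):
    """Base class for all medhaz errors."""


class SchemaError(MedhazError):
    """A required column or field is missing or mis-mapped."""


class InputError(MedhazError):
    """Unusable input (e.g. an empty cohort file)."""


class DomainError(MedhazError, ValueError):
    """An argument lies outside its mathematical domain."""


class InconsistencyError(MedhazError, ValueError):
    """Mutually contradictory raw measurements (e.g. positive grams/day
    for a subject reported as drinking nothing in the past year)."""


class DegenerateDataError(MedhazError):
    """Data too degenerate to fit (single-level mediator, empty cell)."""


class ConvergenceError(MedhazError):
    """Iterative fit failed to converge."""


class PositivityError(MedhazError):
    """A mediator-model probability underflows the positivity bound, so
    a counterfactual weight is undefined."""


class RankError(MedhazError):
    """Integrated design matrix is singular (collinear columns)."""


class GenerationError(MedhazError):
    """Synthetic-cohort parameters produce an invalid data-generating law
    (e.g. too much hazard-rate clipping)."""
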