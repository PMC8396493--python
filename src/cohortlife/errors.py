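"""Exception hierarchy for cohortlife."""


class CohortLifeError(Exception):
    """Base class for all cohortlife errors."""


class ConfigurationError(CohortLifeError, ValueError):
    """A cohort configuration is invalid; the message names the offending field."""


class InputError(CohortLifeError, ValueError):
    """Inputs violate a precondition (mixed diets, mismatched parameters, ...)."""


class ValidationError(InputError):
    """One or more records violate the record invariants.

    ``row_errors`` maps a 1-based data-row number to the list of violations
    found on that row.
    """

    def __init__(self, row_errors: dict[int, list[str]]):
        self.row_errors = dict(row_errors)
        lines = [
            f"row {row}: {'; '.join(msgs)}" for row, msgs in sorted(self.row_errors.items())
        ]
        super().__init__("invalid records:\n" + "\n".join(lines))


class AnalysisError(CohortLifeError, ValueError):
    """A computation is undefined for the given cohort (e.g. no reproducing female)."""


class NumericalError(CohortLifeError, ArithmeticError):
    """A numerical routine failed (e.g. no Euler-Lotka root in the search bracket)."""
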