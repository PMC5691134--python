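"""Exception hierarchy.

``InputError`` covers user-supplied data that violates a precondition
(unknown ids, malformed files); ``ModelValidationError`` covers structural
violations of the network invariants; ``SolverError`` signals that an LP/ILP
backend failed for reasons other than infeasibility, which is never mapped
to a silent zero.
"""


class FluxGamesError(Exception):
    """Base class for all package errors."""


class InputError(FluxGamesError):
    """Invalid user input (unknown reaction/gene/metabolite, bad parameter)."""


class ModelValidationError(FluxGamesError):
    """A metabolic network violates its structural invariants."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class SolverError(FluxGamesError):
    """The optimization backend failed (not infeasibility)."""
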