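"""Exception types shared across the pipeline stages."""


class PinsimError(Exception):
    """Base class for all package errors."""


class ParameterError(PinsimError, ValueError):
    """An input parameter violates its documented constraints."""


class GeometryError(PinsimError, RuntimeError):
    """A mesh or volume does not satisfy a geometric precondition."""


class AssignmentError(PinsimError, RuntimeError):
    """A component could not be assigned to an anatomical role."""


class PlacementError(PinsimError, RuntimeError):
    """One or more wires could not be placed on target.

    Attributes
    ----------
    missed : list of int
        Indices (1-3) of the wires whose line missed the subchondral surface.
    """

    def __init__(self, message, missed=()):
        super().__init__(message)
        self.missed = list(missed)


class DataError(PinsimError, ValueError):
    """Tabular or record-level input is incomplete or inconsistent."""


class ConfigError(PinsimError, ValueError):
    """A run configuration is invalid; message itemizes the offending keys."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
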