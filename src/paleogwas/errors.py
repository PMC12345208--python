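"""Exception hierarchy.

Everything derives from :class:`PaleogwasError` so callers can catch the
package's own failures without swallowing genuine bugs.
"""


class PaleogwasError(Exception):
    """Base class for all errors raised by paleogwas."""


class SchemaError(PaleogwasError):
    """A table is missing required columns or has the wrong shape."""


class IntegrityError(PaleogwasError):
    """Row-level data violates a documented invariant (range, uniqueness)."""


class ContractError(PaleogwasError):
    """A function was called with inputs that violate its preconditions."""


class ParameterError(PaleogwasError):
    """A tuning parameter is outside its admissible range."""


class SpecError(PaleogwasError):
    """A synthetic-data specification is internally inconsistent."""


class InfeasibleStratumError(PaleogwasError):
    """A MAF stratum cannot supply the number of variants a null draw needs."""

    def __init__(self, stratum: str, needed: int, available: int):
        self.stratum = stratum
        self.needed = needed
        self.available = available
        super().__init__(
            f"stratum {stratum}: need {needed} variants but pool holds {available}"
        )
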