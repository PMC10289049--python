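"""Exception types shared across the package."""


class LdlkitError(Exception):
    """Base class for all ldlkit errors."""


class ValidationError(LdlkitError, ValueError):
    """Invalid user input (shapes, values, configuration)."""


class UnknownEquationError(LdlkitError, KeyError):
    """Requested equation id is not in the registry."""

    def __init__(self, eq_id: str, known: tuple[str, ...]):
        self.eq_id = eq_id
        self.known = known
        super().__init__(
            f"unknown equation id {eq_id!r}; registered ids: {', '.join(known)}"
        )


class TGDomainError(LdlkitError, ValueError):
    """Triglyceride value outside an equation's or table's validity domain."""

    def __init__(self, what: str, tg, lo: float, hi: float, hint: str = ""):
        self.what = what
        self.tg = tg
        self.lo = lo
        self.hi = hi
        msg = f"TG value {tg} mg/dL outside the validity domain [{lo}, {hi}) of {what}"
        if hint:
            msg += f"; {hint}"
        super().__init__(msg)


class UnknownStratumError(LdlkitError, KeyError):
    """Requested stratum name is not defined."""

    def __init__(self, name: str, known: tuple[str, ...]):
        self.name = name
        self.known = known
        super().__init__(
            f"unknown stratum {name!r}; available strata: {', '.join(known)}"
        )
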