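"""Exception and warning types shared across the package."""


class DdgiNetError(Exception):
    """Base class for all package errors."""


class ConfigError(DdgiNetError):
    """A configuration document violates the schema (bad structure, missing
    key, wrong type). The message names the offending path."""


class NetworkReferenceError(DdgiNetError):
    """A network entity references a compound/enzyme/pathway that does not
    exist."""


class DomainError(DdgiNetError, ValueError):
    """A value is outside its mathematical domain (non-positive constant,
    negative activity score, empty grid, ...)."""


class IntegrationError(DdgiNetError):
    """The ODE solver failed to converge; carries the solver diagnostic."""


class SteadyStateWarning(UserWarning):
    """Repeated dosing did not satisfy the steady-state criterion within the
    interval cap; the reported AUC_ss is the last simulated interval."""


class MassBalanceWarning(UserWarning):
    """State clipping or mass defect beyond the expected solver noise."""
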