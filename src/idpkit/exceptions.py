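"""Exception hierarchy shared across the toolkit."""


class IdpkitError(Exception):
    """Base class for all idpkit errors."""


class InputError(IdpkitError, ValueError):
    """Raised when an input violates a documented precondition."""


class UndefinedKappaError(InputError):
    """Raised when kappa is requested for a sequence with no charged residues."""


class FitError(IdpkitError, RuntimeError):
    """Raised when a fit fails to converge or is degenerate."""
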