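"""Exception types shared across the package."""


class PolyBigSmilesError(Exception):
    """Base class for all package errors."""


class SmilesSyntaxError(PolyBigSmilesError):
    """A SMILES string violates lexical or structural grammar.

    Parameters
    ----------
    message : str
        Human-readable diagnostic.
    position : int, optional
        0-based character offset of the offending token, when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ContractViolation(PolyBigSmilesError, ValueError):
    """An operation was called outside its documented preconditions."""


class RejectedInput(PolyBigSmilesError):
    """A repeat unit cannot be converted; carries a machine-readable reason.

    Reasons mirror the conversion workflow's filter stages:

    - ``wrong_point_count``: number of polymerization points (asterisks) != 2;
      ``detail`` holds the observed count.
    - ``invalid_grammar``: the string does not parse as a molecular graph.
    - ``no_main_chain``: an asterisk sits mid-chain (a divalent attachment
      point), so no main-chain remainder exists to swap it with.
    - ``unsupported_wildcard_bond``: an asterisk carries an explicit
      non-single bond.
    """

    def __init__(self, reason: str, detail=None, message: str | None = None):
        self.reason = reason
        self.detail = detail
        super().__init__(message or f"rejected: {reason}"
                         + (f" ({detail})" if detail is not None else ""))


class BigSmilesSyntaxError(PolyBigSmilesError):
    """A BigSMILES string does not match any supported homopolymer shape."""
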