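"""Parse homopolymer BigSMILES back to repeat-unit SMILES and compare
structures.

Only the four homopolymer stochastic-object shapes the converter emits are
recognized (full BigSMILES — nested objects, copolymer unit lists, end-group
objects — is out of scope):

========  =======================  =============================
variant   shape                    meaning
========  =======================  =============================
AA        ``{$unit$}``             chain-growth / addition
AB_plain  ``{<unit>}``             step-growth, ends unannotated
AB_split  ``{<A<,>B>}``            step-growth, reactive end groups A and B
AB_two_unit ``{<u1>,<u2>}``        ring-opened epoxide orientations
========  =======================  =============================

Version-1.1 bracketed descriptors (``[$]``, ``[<]``, ``[>]``) are accepted
on input and normalized to the 1.0 forms emitted here.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import smiles_core as sc
from .errors import BigSmilesSyntaxError

__all__ = [
    "normalize_bigsmiles",
    "ParsedBigSmiles",
    "parse_bigsmiles",
    "to_smiles",
    "structurally_equivalent",
]


def normalize_bigsmiles(b: str) -> str:
    """Strip whitespace and rewrite 1.1 bracketed descriptors to 1.0."""
    s = sc._WS_RE.sub("", b)
    return s.replace("[$]", "$").replace("[<]", "<").replace("[>]", ">")


@dataclass(frozen=True)
class ParsedBigSmiles:
    variant: str              # AA | AB_plain | AB_split | AB_two_unit
    units: tuple[str, ...]    # 1 fragment, or 2 for AB_split/AB_two_unit
    descriptors: tuple[str, ...]


_FORBIDDEN = set("{}<>$,")


def _check_fragment(frag: str, b: str) -> None:
    if not frag or set(frag) & _FORBIDDEN:
        raise BigSmilesSyntaxError(
            f"unknown descriptor layout in {b!r}")
    diag = sc.validate_grammar(f"*{frag}*")
    if not diag.ok:
        raise BigSmilesSyntaxError(
            f"fragment {frag!r} of {b!r} is not valid SMILES: "
            f"{diag.violations[0][1]}")


def parse_bigsmiles(b: str) -> ParsedBigSmiles:
    """Recognize one of the four homopolymer shapes; reject anything else."""
    s = normalize_bigsmiles(b)
    if not (s.startswith("{") and s.endswith("}")) or \
            s.count("{") != 1 or s.count("}") != 1:
        raise BigSmilesSyntaxError(
            f"{b!r}: expected a single curly-bracketed stochastic object")
    inner = s[1:-1]
    if inner.startswith("$") and inner.endswith("$"):
        unit = inner[1:-1]
        _check_fragment(unit, b)
        return ParsedBigSmiles("AA", (unit,), ("$", "$"))
    if inner.startswith("<") and inner.endswith(">"):
        body = inner[1:-1]
        if body.count("<,>") == 1 and ">,<" not in body:
            a, bb = body.split("<,>")
            _check_fragment(a, b)
            _check_fragment(bb, b)
            return ParsedBigSmiles("AB_split", (a, bb), ("<", "<,>", ">"))
        if body.count(">,<") == 1 and "<,>" not in body:
            u1, u2 = body.split(">,<")
            _check_fragment(u1, b)
            _check_fragment(u2, b)
            return ParsedBigSmiles("AB_two_unit", (u1, u2),
                                   ("<", ">", ",", "<", ">"))
        _check_fragment(body, b)
        return ParsedBigSmiles("AB_plain", (body,), ("<", ">"))
    raise BigSmilesSyntaxError(f"unknown descriptor layout in {b!r}")


def to_smiles(b: str | ParsedBigSmiles) -> str:
    """Back-convert to a two-point repeat-unit SMILES.

    AA and AB_plain return ``*unit*``; AB_split concatenates the two end
    groups (``*AB*``); AB_two_unit returns the first unit, which carries
    the original orientation.
    """
    parsed = parse_bigsmiles(b) if isinstance(b, str) else b
    if parsed.variant == "AB_split":
        return f"*{parsed.units[0]}{parsed.units[1]}*"
    return f"*{parsed.units[0]}*"


def structurally_equivalent(a: str, b: str) -> bool:
    """Do two representations describe the same polymer?

    Both arguments may be SMILES or BigSMILES (detected by the curly
    bracket).  Equivalence is judged on the rotation-invariant cycle key,
    so ordering, aromatic spelling and whitespace differences are
    tolerated; when both sides are BigSMILES their AA/AB classification
    must also agree.  Unparseable input raises.
    """
    a_big, b_big = "{" in a, "{" in b
    a_smiles = to_smiles(a) if a_big else sc.normalize(a)
    b_smiles = to_smiles(b) if b_big else sc.normalize(b)
    if a_big and b_big:
        va = parse_bigsmiles(a).variant
        vb = parse_bigsmiles(b).variant
        if (va == "AA") != (vb == "AA"):
            return False
    return sc.cycle_key(a_smiles) == sc.cycle_key(b_smiles)
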